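# Published per-condition case counts and statistics for the two state
# cohorts (Florida N=558,224; Texas N=981,120 linked pairs, births
# 1999-2010; NICU restricted to 2004-2010). Counts: cases identified in
# claims (max_count), on the certificate (bc_count), and by both.
# denominator_policy records which analysis denominator reproduces the
# printed kappa: the state total, a denominator reconstructed from the
# row's printed claims- or certificate-side prevalence, or an explicit
# shared sub-cohort denominator. reproducible marks whether the printed
# kappa is recovered under that policy; non-reproducing rows keep their
# printed values unaltered. This file is a frozen fixture: edits break
# the checksum test.
state,condition,max_count,bc_count,both_count,kappa_pct,sens_max,sens_bc,prev_max_per100,prev_bc_per100,denominator_policy,denominator,reproducible
FL,NICU,20548,17524,11185,55.7,0.64,0.54,7.40,6.31,reconstructed_from_max_prev,,true
FL,RDS,14673,2933,1450,15.7,0.49,0.10,2.72,0.54,state_total,,true
FL,SEIZURE,1236,85,56,8.4,0.66,0.05,0.24,0.02,state_total,,false
FL,AV,6933,17039,1932,14.5,0.11,0.28,1.27,3.14,state_total,,false
FL,BIRTH_INJURY,8311,333,73,1.5,0.22,0.01,1.54,0.06,state_total,,false
TX,NICU,62258,42592,34577,62.8,0.81,0.56,10.00,7.05,reconstructed_from_bc_prev,,true
TX,RDS,17897,3276,2100,18.6,0.64,0.12,4.74,0.87,reconstructed_from_max_prev,,true
TX,SEIZURE,2531,239,143,10.2,0.60,0.06,0.25,0.02,shared_subcohort,377574,true
TX,AV,23311,50969,6900,15.8,0.14,0.30,2.37,5.19,state_total,,true
TX,BIRTH_INJURY,11427,312,101,1.6,0.32,0.01,1.89,0.05,reconstructed_from_max_prev,,true
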