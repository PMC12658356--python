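name,base,lower,upper,dist
hr_mrs0,1.53,1.23,1.83,lognormal
hr_mrs1,1.52,1.20,1.83,lognormal
hr_mrs2,2.17,2.14,2.20,lognormal
hr_mrs3,3.18,3.17,3.19,lognormal
hr_mrs4,4.55,4.31,4.78,lognormal
hr_mrs5,6.55,6.12,6.98,lognormal
recurrence_y1,0.059,,,fixed
recurrence_y2,0.036,,,fixed
recurrence_y3,0.025,,,fixed
recurrence_y4,0.022,,,fixed
recurrence_y5,0.022,,,fixed
recurrence_y6,0.027,,,fixed
recurrence_y7,0.027,,,fixed
recurrence_y8,0.023,,,fixed
recurrence_y9,0.028,,,fixed
recurrence_y10plus,0.016,,,fixed
cost_edsl_tablet,70,63,77,gamma
cost_edcsi_vial,29.68,,,fixed
cost_iv_drip,8.11,7,10,gamma
cost_hospitalization_mrs02,12995.74,12804.46,13189.61,gamma
cost_hospitalization_mrs35,17744.26,17355.23,18139.75,gamma
cost_hospitalization_mrs6,14373.51,13207.70,15614.28,gamma
cost_poststroke_mrs02,9544.86,9248.88,9847.29,gamma
cost_poststroke_mrs35,14669.48,13868.15,15504.42,gamma
cost_bun,6.28,4.00,7.73,gamma
cost_creatinine,6.51,4.00,7.73,gamma
hospital_days,10,,,fixed
monitoring_frequency,1,0.9,1.1,gamma
utility_mrs0,0.983,0.981,0.985,beta
utility_mrs1,0.894,0.892,0.896,beta
utility_mrs2,0.679,0.675,0.683,beta
utility_mrs3,0.556,0.551,0.561,beta
utility_mrs4,0.270,0.263,0.277,beta
utility_mrs5,0.058,0.051,0.065,beta
disutility_stroke,0.086,0.06,0.112,beta
disutility_drip,0.023,0.0207,0.0253,beta
discount_rate_cost,0.05,0.00,0.08,uniform
discount_rate_utility,0.05,0.00,0.08,uniform
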