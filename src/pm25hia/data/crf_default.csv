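# Default concentration-response parameter registry (age-pooled, adults 25+).
# GEMM rows: theta/theta_se/alpha/mu/nu from the published GEMM cohort
# synthesis (age-pooled hazard curves per cause). Log-linear rows: per-ug/m3
# admission coefficients with 95% CI, defaults drawn from national
# time-series evidence; z0=0 (no threshold). Replace with study-specific
# values for any real analysis.
function_family,cause,age_group,theta,theta_se,alpha,mu,nu,beta,beta_low,beta_high,z0
gemm,NCD+LRI,all-25plus,0.1430,0.01807,1.6,15.5,36.8,,,,
gemm,IHD,all-25plus,0.2969,0.01787,1.9,12.0,40.2,,,,
gemm,stroke,all-25plus,0.2720,0.07697,6.2,16.7,23.7,,,,
gemm,COPD,all-25plus,0.2510,0.06762,6.5,2.5,32.0,,,,
gemm,LC,all-25plus,0.2942,0.06147,6.2,9.3,29.8,,,,
gemm,LRI,all-25plus,0.4468,0.11735,6.4,5.7,8.4,,,,
loglinear,cardiovascular,all-25plus,,,,,,0.00068,0.00043,0.00093,0
loglinear,respiratory,all-25plus,,,,,,0.00082,0.00052,0.00112,0
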