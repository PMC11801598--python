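equation_id,term,value,center
always,__form__,constant_prob,
always,__intercept__,1.0,
death_all,__form__,ph_weibull,
death_all,__intercept__,-7.2755,
death_all,__shape__,2.0,
death_all,bmi,0.02,35.9
death_all,egfr,-0.005,77.5
death_all,female,-0.22,0.0
death_all,hba1c_pct,0.06,8.3
death_all,prior_amputation,0.5,0.0
death_all,prior_esrd,1.1,0.0
death_all,prior_hf,0.6,0.0
death_all,prior_mi,0.4,0.0
death_all,prior_stroke,0.4,0.0
death_all,sbp,0.004,143.2
death_all,smoker,0.29,0.0
death_cv,__form__,ph_exponential,
death_cv,__intercept__,-4.8742,
death_cv,hba1c_pct,0.05,8.3
death_cv,prior_mi,1.8,0.0
death_cv,prior_stroke,1.6,0.0
death_cv,sbp,0.004,143.2
eye_bdr,__form__,ph_exponential,
eye_bdr,__intercept__,-3.661,
eye_bdr,hba1c_pct,1.0,8.3
eye_bdr,sbp,0.008,143.2
eye_me,__form__,ph_exponential,
eye_me,__intercept__,-2.3527,
eye_me,hba1c_pct,0.7,8.3
eye_pdr,__form__,ph_exponential,
eye_pdr,__intercept__,-4.1165,
eye_pdr,hba1c_pct,1.6,8.3
eye_pdrme,__form__,ph_exponential,
eye_pdrme,__intercept__,-3.9644,
eye_pdrme,hba1c_pct,1.4,8.3
eye_svl,__form__,ph_exponential,
eye_svl,__intercept__,-3.4138,
eye_svl,hba1c_pct,0.15,8.3
hf_first,__form__,ph_exponential,
hf_first,__intercept__,-5.0473,
hf_first,bmi,0.04,35.9
hf_first,hba1c_pct,0.03,8.3
hf_first,sbp,0.005,143.2
ihd_first,__form__,ph_exponential,
ihd_first,__intercept__,-4.4595,
ihd_first,hba1c_pct,0.02,8.3
ihd_first,ldl,0.15,2.75
ihd_first,sbp,0.004,143.2
lex_amputation,__form__,ph_exponential,
lex_amputation,__intercept__,-0.7,
lex_amputation,hba1c_pct,0.1,8.3
lex_neuropathy,__form__,ph_exponential,
lex_neuropathy,__intercept__,-5.6455,
lex_neuropathy,bmi,0.03,35.9
lex_neuropathy,hba1c_pct,0.6,8.3
lex_pvd,__form__,ph_exponential,
lex_pvd,__intercept__,-4.4776,
lex_pvd,hba1c_pct,0.02,8.3
lex_pvd,smoker,0.3,0.0
mi_first,__form__,ph_exponential,
mi_first,__intercept__,-4.0739,
mi_first,female,-0.35,0.0
mi_first,hba1c_pct,0.065,8.3
mi_first,hdl,-0.6,1.21
mi_first,sbp,0.009,143.2
mi_first,smoker,0.35,0.0
mi_subsequent_eq,__form__,ph_exponential,
mi_subsequent_eq,__intercept__,-3.936,
mi_subsequent_eq,hba1c_pct,0.05,8.3
renal_esrd,__form__,ph_exponential,
renal_esrd,__intercept__,-2.334,
renal_esrd,egfr,-0.01,77.5
renal_esrd,hba1c_pct,0.6,8.3
renal_macro,__form__,ph_exponential,
renal_macro,__intercept__,-2.1972,
renal_macro,hba1c_pct,1.0,8.3
renal_macro,sbp,0.008,143.2
renal_micro,__form__,ph_exponential,
renal_micro,__intercept__,-4.1137,
renal_micro,hba1c_pct,0.45,8.3
renal_micro,sbp,0.006,143.2
stroke_first,__form__,ph_exponential,
stroke_first,__intercept__,-5.0934,
stroke_first,hba1c_pct,0.08,8.3
stroke_first,sbp,0.012,143.2
stroke_first,smoker,0.35,0.0
stroke_subsequent_eq,__form__,ph_exponential,
stroke_subsequent_eq,__intercept__,-2.8567,
stroke_subsequent_eq,hba1c_pct,0.08,8.3
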