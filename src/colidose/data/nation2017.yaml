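# Default maintenance-dose model: daily dose of colistin base activity
# (mg CBA/day) per 1 mg/L of target colistin Css,avg, by Cockcroft-Gault
# creatinine-clearance band.  Transcribed from the dosing table of the 2017
# population-pharmacokinetic dosing guidance for intravenous colistin in
# critically ill patients (Nation RL et al., Clin Infect Dis 2017;64:565-571).
# Each band applies to CrCl < crcl_upper (mL/min); the final band is open.
name: nation2017
interpolate: false
max_daily_cba: 300
bands:
  - {crcl_upper: 5, dose_per_unit_css: 130}
  - {crcl_upper: 10, dose_per_unit_css: 145}
  - {crcl_upper: 20, dose_per_unit_css: 160}
  - {crcl_upper: 30, dose_per_unit_css: 175}
  - {crcl_upper: 40, dose_per_unit_css: 195}
  - {crcl_upper: 50, dose_per_unit_css: 220}
  - {crcl_upper: 60, dose_per_unit_css: 245}
  - {crcl_upper: 70, dose_per_unit_css: 275}
  - {crcl_upper: 80, dose_per_unit_css: 300}
  - {crcl_upper: 90, dose_per_unit_css: 340}
  - {crcl_upper: .inf, dose_per_unit_css: 360}
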