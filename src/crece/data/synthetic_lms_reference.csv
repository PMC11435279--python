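# SYNTHETIC LMS reference table for tests and examples.
# These L/M/S rows are shaped like a pediatric growth reference
# (BMI-for-age in kg/m^2, MUAC-for-age in cm, ages in months) but are
# NOT any published reference; supply a real CDC/WHO-style table for
# actual use.
metric,sex,age_months,L,M,S
bmi_age,male,36,-1.6,16.2,0.080
bmi_age,male,42,-1.7,16.0,0.081
bmi_age,male,48,-1.8,15.8,0.082
bmi_age,male,54,-1.9,15.7,0.084
bmi_age,male,60,-2.0,15.6,0.086
bmi_age,female,36,-1.5,16.0,0.082
bmi_age,female,42,-1.6,15.8,0.084
bmi_age,female,48,-1.7,15.6,0.086
bmi_age,female,54,-1.8,15.5,0.088
bmi_age,female,60,-1.9,15.4,0.090
muac_age,male,36,-0.4,16.0,0.070
muac_age,male,42,-0.4,16.2,0.071
muac_age,male,48,-0.5,16.4,0.072
muac_age,male,54,-0.5,16.6,0.073
muac_age,male,60,-0.6,16.8,0.074
muac_age,female,36,-0.3,15.8,0.072
muac_age,female,42,-0.3,16.0,0.073
muac_age,female,48,-0.4,16.2,0.074
muac_age,female,54,-0.4,16.4,0.075
muac_age,female,60,-0.5,16.6,0.076
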