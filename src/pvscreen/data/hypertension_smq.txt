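# Default hypertension event term set (MedDRA-PT-style, uppercase).
# Stand-in for the licensed SMQ narrow-term list; override with any
# plain-text term file, one preferred term per line.
HYPERTENSION
BLOOD PRESSURE INCREASED
HYPERTENSIVE CRISIS
HYPERTENSIVE EMERGENCY
HYPERTENSIVE ENCEPHALOPATHY
BLOOD PRESSURE SYSTOLIC INCREASED
BLOOD PRESSURE DIASTOLIC INCREASED
LABILE HYPERTENSION
ESSENTIAL HYPERTENSION
ACCELERATED HYPERTENSION
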