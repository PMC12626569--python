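pt_code,pt_name
10051055,Deep vein thrombosis
10037377,Pulmonary embolism
10047249,Venous thrombosis
10014522,Embolism venous
10034272,Pelvic venous thrombosis
10062506,Venous thrombosis limb
10051239,Axillary vein thrombosis
10058990,Subclavian vein thrombosis
10044457,Thrombosis
10064000,Jugular vein thrombosis
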