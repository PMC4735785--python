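Patient	Translocation_diagnosis	Translocation_relapse
SCMC-000206	t(12;21);t(5;12);t(5;21)	t(12;21);t(5;12);t(5;21)
SCMC-000863	t(12;21);t(5;12);t(5;21)	t(12;21);t(5;12);t(5;21)
SCMC-000966	t(12;21);t(6;12);t(6;21)	t(12;21);t(6;12);t(6;21)
SCMC-001245	t(12;21);t(8;12);t(8;21)	t(12;21)
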