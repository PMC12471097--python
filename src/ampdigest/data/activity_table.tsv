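activity	fragment	source_ids
ACE inhibitor	AR	AP00236
ACE inhibitor	PGL	AP00984
ACE inhibitor	CF	AP00984
ACE inhibitor	EK	AP00984;AP02329
ACE inhibitor	TF	AP00979
ACE inhibitor	IL	AP00979
ACE inhibitor	GL	AP01026;AP01124;AP01784;AP01785;AP01806;AP01807;AP02332;AP02657
ACE inhibitor	IY	AP01277;AP01278;AP01279;AP01280;AP01281;AP01282;AP01284;AP01328
ACE inhibitor	ER	AP01280;AP01282;AP01284;AP01328
ACE inhibitor	VF	AP01343
ACE inhibitor	AW	AP01805
ACE inhibitor	PL	AP02657
ACE inhibitor	GK	AP02328
ACE inhibitor	GF	AP05050
Antioxidative	PK	AP00236
Antioxidative	TW	AP00236
Antioxidative	IY	AP01277;AP01278;AP01279;AP01280;AP01281;AP01282;AP01284;AP01328
Antioxidative	AW	AP01805
Antioxidative	PW	AP01986;AP01988
Dipeptidyl peptidase IV inhibitor	PK	AP00236;AP01278;AP01279;AP01280;AP01281;AP01282;AP01284;AP01328
Dipeptidyl peptidase IV inhibitor	TW	AP00236
Dipeptidyl peptidase IV inhibitor	EK	AP00984;AP02329
Dipeptidyl peptidase IV inhibitor	IL	AP00979
Dipeptidyl peptidase IV inhibitor	TF	AP00979
Dipeptidyl peptidase IV inhibitor	GL	AP01026;AP01124;AP01784;AP01785;AP01806;AP01807;AP02332;AP02657
Dipeptidyl peptidase IV inhibitor	SK	AP01036;AP01123;AP01124;AP01774;AP01777;AP01808;AP01813;AP01983;AP02329;AP05050
Dipeptidyl peptidase IV inhibitor	VF	AP01343
Dipeptidyl peptidase IV inhibitor	AW	AP01805
Dipeptidyl peptidase IV inhibitor	PF	AP01985
Dipeptidyl peptidase IV inhibitor	PW	AP01986;AP01988
Dipeptidyl peptidase IV inhibitor	IM	AP02329
Dipeptidyl peptidase IV inhibitor	QH	AP02329
Dipeptidyl peptidase IV inhibitor	QL	AP02329
Dipeptidyl peptidase IV inhibitor	PL	AP02657
Dipeptidyl peptidase IV inhibitor	GF	AP05050
Stimulating	IL	AP00979
Renin inhibitor	TF	AP00979
Dipeptidyl peptidase III inhibitor	TF	AP00979
Dipeptidyl peptidase III inhibitor	PF	AP01985
Dipeptidyl peptidase III inhibitor	GF	AP05050
Neuropeptide	IL	AP00979
ACE2 inhibitor	PF	AP01985
Xaa-Pro inhibitor	PL	AP02657
Lactocepin inhibitor	PL	AP02657
Acylaminoacyl peptidase inhibitor	GF	AP05050
Tripeptidyl peptidase II inhibitor	GF	AP05050
Neprilysin inhibitor	AR	AP00236
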