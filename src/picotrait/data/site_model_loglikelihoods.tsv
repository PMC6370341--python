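gene	taxa	dn_ds	M0	M1	M2	M7	M8
gyrB	226	0.036	-105998	-101367	-101367	-102434	-100472
pstB	200	0.045	-39945	-39466	-39466	-38543	-38484
amtB	200	0.066	-70319	-68351	-68234	-68226	-67620
glnA	229	0.031	-66948	-65905	-65905	-65462	-65118
glsF	215	0.103	-267696	-249591	-249591	-253085	-246724
napA	76	0.054	-23709	-23028	-23028	-23201	-22961
narB	78	0.119	-40791	-38790	-38790	-39102	-38498
moaA	67	0.206	-24794	-22973	-22931	-23268	-22770
focA	60	0.078	-18477	-17701	-17701	-17895	-17615
nirA	115	0.109	-54829	-52361	-52361	-52063	-51470
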