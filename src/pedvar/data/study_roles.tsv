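id	sequenced	control
sire1	1	0
dam1	1	0
puppy1	1	0
puppy4	1	0
sire2	1	0
dam2	1	0
puppy7	1	0
puppy8	1	0
sire3	1	0
dam3	1	0
puppy13	1	0
puppy14	1	0
saluki1	0	1
saluki2	0	1
saluki3	0	1
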