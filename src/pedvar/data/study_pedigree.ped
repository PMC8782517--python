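#family	id	sire	dam	sex	phenotype
NEB	sire1	0	0	1	1
NEB	dam1	0	0	2	1
NEB	sire2	0	0	1	1
NEB	dam2	0	0	2	1
NEB	sire3	0	0	1	1
NEB	dam3	0	0	2	1
NEB	sire4	0	0	1	1
NEB	dam4	0	0	2	1
NEB	sire5	0	0	1	1
NEB	puppy1	sire1	dam1	1	2
NEB	puppy2	sire1	dam1	2	2
NEB	puppy3	sire1	dam1	2	2
NEB	puppy4	sire1	dam1	1	1
NEB	puppy5	sire1	dam1	2	1
NEB	puppy6	sire1	dam1	2	1
NEB	puppy7	sire2	dam2	2	2
NEB	puppy8	sire2	dam2	2	1
NEB	puppy9	sire2	dam2	1	1
NEB	puppy10	sire2	dam2	2	1
NEB	puppy11	sire2	dam2	2	1
NEB	puppy12	sire2	dam2	2	1
NEB	puppy13	sire3	dam3	1	2
NEB	puppy14	sire3	dam3	2	1
NEB	puppy15	sire4	dam4	2	2
NEB	puppy16	sire4	dam4	1	1
NEB	puppy17	sire5	puppy5	1	2
NEB	puppy18	sire5	puppy5	2	2
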