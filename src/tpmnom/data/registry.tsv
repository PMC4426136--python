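short_name	formal_name	gene	tissue	exon_code	common_names	alternate_names	acc_human	acc_mouse	acc_rat
Tpm1.1	Tpm1.1st (a.b.b.a)	1	st	a.b.b.a	Tm skα	αTm|fast skTm|cardiac Tm|striated Tm	NP_001018005.1	NP_001157720.1	NP_001288265.1
Tpm1.2	Tpm1.2st (a.a.b.a)	1	st	a.a.b.a	Tm skα1	κTm|Tmskα1-1	NP_001288173.1	none	NP_001288271.1
Tpm1.3	Tpm1.3sm (a.a.a.d)	1	sm	a.a.a.d	Tm smα-1	α smooth Tm	NP_001018020.1	none	NP_001029243.1
Tpm1.4	Tpm1.4sm (a.a.b.d)	1	sm	a.a.b.d	Tm smα	Tm6|α smooth Tm|Tm α1.2	NP_001018007.1	NP_001157721.1	AAA21804.1
Tpm1.5	Tpm1.5cy (a.b.a.a)	1	cy	a.b.a.a	Tm3-1		NP_000357.3	NP_001157723.1	none
Tpm1.6	Tpm1.6cy (a.b.b.d)	1	cy	a.b.b.d	Tm2		NP_001018004.1	NP_077745.2	NP_001029241.1
Tpm1.7	Tpm1.7cy (a.b.a.d)	1	cy	a.b.a.d	Tm3	Tm 1.4	NP_001018006.1	NP_001157722.1	NP_001029242.1
Tpm1.8	Tpm1.8cy (b.-.b.d)	1	cy	b.-.b.d	Tm5a		NP_001288218.1	NP_001157724.1	NP_001029245.1
Tpm1.9	Tpm1.9cy (b.-.a.d)	1	cy	b.-.a.d	Tm5b		none	NP_001157725.1	NP_001029246.1
Tpm1.10	Tpm1.10br (a.b.b.c)	1	br	a.b.b.c	TmBr1		none	NP_001157727.1	NP_001029244.1
Tpm1.11	Tpm1.11br (b.-.b.b)	1	br	b.-.b.b	TmBr2		none	none	NP_062004.1
Tpm1.12	Tpm1.12br (b.-.b.c)	1	br	b.-.b.c	TmBr3	Tmbrα|Tmbrα-1|Tm α-1.6	NP_001018008.1	NP_001157728.1	NP_001288665.1
Tpm1.13	Tpm1.13 (b.-b.a)	1		b.-.b.a			none	NP_001157726.1	NP_001029247.1
Tpm3.12	Tpm3.12st (a.b.b.a)	3	st	a.b.b.a	Tm skα-slow|γTm	αsTm1|slow skTm	NP_689476.2	NP_001280677.2	NP_001288214.1
Tpm3.13	Tpm3.13cy (a.b.a.d)	3	cy	a.b.a.d			none	NP_071709.2	none
Tpm3.1	Tpm3.1cy(b.-.a.d)	3	cy	b.-.a.d	Tm5NM1		NP_705935.1	NP_001240667.1	NP_775134.1
Tpm3.2	Tpm3.2cy(b.-.b.d)	3	cy	b.-.b.d	Tm5NM2		NP_001036816.1	NP_001240669.1	none
Tpm3.3	Tpm3.3cy(b.-.b.a)	3	cy	b.-.b.a	Tm5NM3		EAW53237.1	none	NP_001288215.1
Tpm3.4	Tpm3.4cy (b.-.b.c)	3	cy	b.-.b.c	Tm5NM4		NP_001036818.1	NP_001280678.1	NP_476556.2
Tpm3.5	Tpm3.5cy(b.-.a.a)	3	cy	b.-.a.a	Tm5NM5		NP_001265118.1	NP_001258693.1	none
Tpm3.7	Tpm3.7cy (b.-.a.c)	3	cy	b.-.a.c	Tm5NM7		NP_001036817.1	none	none
Tpm3.8	Tpm3.8cy (b.-.a.a/c)	3	cy	b.-.a.a/c	Tm5NM8		none	none	none
Tpm3.9	Tpm3.9cy (b.-.b.a/c)	3	cy	b.-.b.a/c	Tm5NM9		none	none	none
Tpm2.1	Tpm2.1sm/cy (a.b.a.d)	2	sm/cy	a.b.a.d	Tm smβ	βTm|Tm1|Tm1β|smooth Tm|smooth α-Tm	NP_998839.1	NP_001264805.1	NP_001019516.1
Tpm2.2	Tpm2.2st (a.b.b.a)	2	st	a.b.b.a	Tm skβ	β skeletal Tm|β cardiac Tm	NP_003280.2	NP_033442.2	NP_001288164.1
Tpm2.3	Tpm2.3 (a.b.b.d)	2		a.b.b.d			NP_001288155.1	NP_001264804.1	none
Tpm2.4	Tpm2.4(a.b.a.a)	2		a.b.a.a			NP_001288156.1	none	none
Tpm4.1	Tpm4.1cy (a.b.b.d)	4	cy	a.b.b.d	Tm4HMW	δTm	NP_001138632.1	none	none
Tpm4.2	Tpm4.2cy (b.-.b.d)	4	cy	b.-.b.d	Tm4		NP_003281.1	NP_001001491.1	NP_036810.1
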