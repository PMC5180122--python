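# Primary (morphology-only) and secondary (sequencing + morphological
# re-examination) identifications for the 15 deep-sea Antarctic polychaete
# morphospecies of the bundled survey, with MB species labels, per-row
# cryptic flags, origin annotations and per-locus sequence counts.
primary	secondary	mb_label	cryptic	origin	n_coi	n_16s
Flabelligena sp. A	Flabelligena sp. A	MB	no	retained	8	12
Flabelligena sp. B	Flabelligena sp. B	MB	no	retained	2	8
Chaetozone sp. A	Chaetozone sp.	MB1a	no	retained	0	7
Chaetozone sp. A	Chaetozone sp.	MB1b	no	retained	0	1
Chaetozone sp. A	Chaetozone sp.	MB1c	no	retained	0	2
Euphrosinella cirratoformis	Euphrosinella cf. cirratoformis	MB1	yes	retained	0	10
Euphrosinella cirratoformis	Euphrosinella cf. cirratoformis	MB2	yes	cryptic_split	0	3
Euphrosinella cirratoformis	Euphrosinopsis cf. antarctica	MB	no	morphological_reassignment	0	2
Glycera capitata	Glycera sp.	MB1	yes	retained	4	15
Glycera capitata	Glycera sp.	MB2	yes	cryptic_split	9	17
Hesionidae sp. A	Hesionidae sp.	MB1	yes	retained	5	24
Hesionidae sp. A	Hesionidae sp.	MB2	yes	cryptic_split	8	0
Lumbrineris kerguelensis-cingulata	Lumbrineris kerguelensis-cingulata	MB1a	no	retained	0	5
Lumbrineris kerguelensis-cingulata	Lumbrineris kerguelensis-cingulata	MB1b	no	retained	0	1
Lumbrineris kerguelensis-cingulata	Lumbrineris kerguelensis-cingulata	MB1c	no	retained	0	5
Lumbrineris kerguelensis-cingulata	Lumbrineris kerguelensis-cingulata	MB1d	no	retained	0	2
Lumbrineris kerguelensis-cingulata	Lumbrineris kerguelensis-cingulata	MB1e	no	retained	0	1
Lumbrineris kerguelensis-cingulata	Lumbrineris kerguelensis-cingulata	MB1f	no	retained	0	2
Maldane sarsi	Maldane sarsi antarctica	MB	yes	retained	0	2
Maldane sarsi	Asychis amphiglyptus	MB	no	morphological_reassignment	0	4
Maldane sarsi	Eupraxillella cf. antarctica	MB	no	morphological_reassignment	0	5
Maldane sarsi	Maldanidae sp.	MB	no	morphological_reassignment	0	1
Maldane sarsi	Praxillella sp.	MB	no	morphological_reassignment	0	1
Aglaophamus trissophyllus	Aglaophamus cf. trissophyllus	MB1a	yes	retained	3	8
Aglaophamus trissophyllus	Aglaophamus cf. trissophyllus	MB1b	yes	retained	2	0
Aglaophamus trissophyllus	Aglaophamus cf. trissophyllus	MB1c	yes	retained	1	0
Aglaophamus trissophyllus	Aglaophamus sp.	MB2	yes	cryptic_split	3	22
Aglaophamus trissophyllus	Aglaophamus sp.	MB3	yes	cryptic_split	2	0
Aglaophamus trissophyllus	Aglaophamus sp.	MB4	no	morphological_reassignment	0	1
Aricidea simplex	Aricidea simplex	MB	no	retained	0	9
Aricidea simplex	Aricidea cf. belgicae	MB1	yes	morphological_reassignment	0	10
Aricidea simplex	Aricidea cf. belgicae	MB2	yes	cryptic_split	0	2
Aricidea simplex	Aricidea cf. belgicae	MB3	yes	cryptic_split	0	1
Aricidea simplex	Aricidea cf. pulchra	MB	no	morphological_reassignment	0	1
Harmothoe fuligineum	Harmothoe fuligineum	MB	no	retained	6	15
Macellicephala sp. A	Macellicephala sp.	MB1	yes	retained	3	9
Macellicephala sp. A	Macellicephala sp.	MB2	yes	cryptic_split	1	3
Macellicephaloides sp. B	Macellicephaloides sp.	MB1a	no	retained	0	12
Macellicephaloides sp. B	Macellicephaloides sp.	MB1b	no	retained	0	2
Scalibregma inflatum	Scalibregma sp.	MB1	yes	retained	6	14
Scalibregma inflatum	Scalibregma sp.	MB2	yes	cryptic_split	1	1
Scalibregma inflatum	Scalibregma sp.	MB3	yes	cryptic_split	3	4
Laonice weddellia	Laonice weddellia	MB	no	retained	7	23
Laonice weddellia	Laonice cf. antarctica	MB	no	morphological_reassignment	2	6
Laonice weddellia	Laonice cf. vieitezi	MB	no	morphological_reassignment	0	5
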