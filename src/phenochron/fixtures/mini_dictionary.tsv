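source_code	icd_code	hpo_id
Seizure disorder	G40.909	HP:0001250
Epilepsy, unspecified, not intractable	G40.909	HP:0001250
Generalized epilepsy	G40.309	HP:0002197
Focal seizure	G40.209	HP:0007359
Localization-related epilepsy	G40.109	HP:0007359
Absence seizure	G40.A09	HP:0002121
Myoclonic seizure	G40.409	HP:0002123
Generalized tonic-clonic seizure	G40.409	HP:0002069
Tonic seizure	G40.409	HP:0010818
Atonic seizure	G40.409	HP:0010819
Febrile convulsion	R56.00	HP:0002373
Complex febrile seizure	R56.01	HP:0002373
Status epilepticus	G40.901	HP:0002133
Infantile spasms	G40.821	HP:0012469
Epileptic spasms	G40.821	HP:0011097
Neonatal seizure onset	P90	HP:0003623
Global developmental delay	F88	HP:0001263
Developmental regression	F84.3	HP:0002376
Intellectual disability	F79	HP:0001249
Mild intellectual disability	F70	HP:0001256
Moderate intellectual disability	F71	HP:0002342
Severe intellectual disability	F72	HP:0010864
Severe intellectual disability	F72	HP:0012828
Speech delay	R47.9	HP:0000750
Speech and language disorder	F80.9	HP:0002167
Dysarthria	R47.1	HP:0001260
Attention deficit hyperactivity disorder	F90.0	HP:0007018
Autism spectrum disorder	F84.0	HP:0000729
Aggressive behavior	R45.6	HP:0000718
Anxiety disorder	F41.9	HP:0000739
Insomnia	G47.00	HP:0002360
Hypotonia	R29.898	HP:0001252
Congenital hypotonia	P94.2	HP:0001290
Spastic quadriplegia	G80.0	HP:0001257
Ataxia	R27.0	HP:0001251
Dystonia	G24.9	HP:0001332
Tremor	R25.1	HP:0001337
Chorea	G25.5	HP:0002072
Gait abnormality	R26.9	HP:0001288
Microcephaly	Q02	HP:0000252
Macrocephaly	Q75.3	HP:0000256
Cerebral atrophy	G31.9	HP:0002059
Encephalopathy, unspecified	G93.40	HP:0001298
Abnormal EEG	R94.01	HP:0002353
Headache	R51.9	HP:0002315
Migraine	G43.909	HP:0002076
Strabismus	H50.9	HP:0000486
Nystagmus	H55.00	HP:0000639
Neurology follow-up visit	R62.50	
Altered mental status	R41.82	
Well child examination	Z00.129	
Asthma exacerbation	J45.901	
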