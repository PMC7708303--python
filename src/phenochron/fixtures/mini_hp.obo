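format-version: 1.2
data-version: fixture/mini
ontology: hp
remark: Synthetic miniature slice of the Human Phenotype Ontology for testing.
remark: Term ids and names follow real HPO accessions; the is_a structure is a
remark: simplified (not authoritative) subset.

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000118
name: Phenotypic abnormality
is_a: HP:0000001 ! All

[Term]
id: HP:0000707
name: Abnormality of the nervous system
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0012638
name: Abnormal nervous system physiology
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0012639
name: Abnormal nervous system morphology
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0001250
name: Seizure
alt_id: HP:0001275
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0002197
name: Generalized-onset seizure
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0007359
name: Focal-onset seizure
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0002121
name: Absence seizure
is_a: HP:0002197 ! Generalized-onset seizure

[Term]
id: HP:0002123
name: Generalized myoclonic seizure
is_a: HP:0002197 ! Generalized-onset seizure

[Term]
id: HP:0010818
name: Generalized tonic seizure
is_a: HP:0002197 ! Generalized-onset seizure

[Term]
id: HP:0010819
name: Atonic seizure
is_a: HP:0002197 ! Generalized-onset seizure

[Term]
id: HP:0002069
name: Bilateral tonic-clonic seizure
is_a: HP:0002197 ! Generalized-onset seizure
is_a: HP:0007359 ! Focal-onset seizure

[Term]
id: HP:0002373
name: Febrile seizure
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0002133
name: Status epilepticus
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0011097
name: Epileptic spasm
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0012469
name: Infantile spasms
is_a: HP:0011097 ! Epileptic spasm

[Term]
id: HP:0012759
name: Neurodevelopmental abnormality
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0001249
name: Intellectual disability
is_a: HP:0012759 ! Neurodevelopmental abnormality

[Term]
id: HP:0001256
name: Intellectual disability, mild
is_a: HP:0001249 ! Intellectual disability

[Term]
id: HP:0002342
name: Intellectual disability, moderate
is_a: HP:0001249 ! Intellectual disability

[Term]
id: HP:0010864
name: Intellectual disability, severe
is_a: HP:0001249 ! Intellectual disability

[Term]
id: HP:0001263
name: Global developmental delay
is_a: HP:0012759 ! Neurodevelopmental abnormality

[Term]
id: HP:0002376
name: Developmental regression
is_a: HP:0012759 ! Neurodevelopmental abnormality

[Term]
id: HP:0000708
name: Behavioral abnormality
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0007018
name: Attention deficit hyperactivity disorder
is_a: HP:0000708 ! Behavioral abnormality

[Term]
id: HP:0000729
name: Autistic behavior
is_a: HP:0000708 ! Behavioral abnormality

[Term]
id: HP:0000718
name: Aggressive behavior
is_a: HP:0000708 ! Behavioral abnormality

[Term]
id: HP:0000739
name: Anxiety
is_a: HP:0000708 ! Behavioral abnormality

[Term]
id: HP:0002360
name: Sleep disturbance
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0100022
name: Abnormality of movement
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0001252
name: Hypotonia
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0001290
name: Generalized hypotonia
is_a: HP:0001252 ! Hypotonia

[Term]
id: HP:0001276
name: Hypertonia
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0001257
name: Spasticity
is_a: HP:0001276 ! Hypertonia

[Term]
id: HP:0001251
name: Ataxia
is_a: HP:0100022 ! Abnormality of movement

[Term]
id: HP:0001332
name: Dystonia
is_a: HP:0100022 ! Abnormality of movement

[Term]
id: HP:0001337
name: Tremor
is_a: HP:0100022 ! Abnormality of movement

[Term]
id: HP:0002072
name: Chorea
is_a: HP:0100022 ! Abnormality of movement

[Term]
id: HP:0001288
name: Gait disturbance
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0002167
name: Neurological speech impairment
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0001260
name: Dysarthria
is_a: HP:0002167 ! Neurological speech impairment

[Term]
id: HP:0000750
name: Delayed speech and language development
is_a: HP:0002167 ! Neurological speech impairment
is_a: HP:0012759 ! Neurodevelopmental abnormality

[Term]
id: HP:0000252
name: Microcephaly
is_a: HP:0012639 ! Abnormal nervous system morphology

[Term]
id: HP:0000256
name: Macrocephaly
is_a: HP:0012639 ! Abnormal nervous system morphology

[Term]
id: HP:0002059
name: Cerebral atrophy
is_a: HP:0012639 ! Abnormal nervous system morphology

[Term]
id: HP:0001298
name: Encephalopathy
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0002353
name: EEG abnormality
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0002315
name: Headache
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0002076
name: Migraine
is_a: HP:0002315 ! Headache

[Term]
id: HP:0000478
name: Abnormality of the eye
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000486
name: Strabismus
is_a: HP:0000478 ! Abnormality of the eye

[Term]
id: HP:0000639
name: Nystagmus
is_a: HP:0000478 ! Abnormality of the eye

[Term]
id: HP:0012823
name: Clinical modifier
is_a: HP:0000001 ! All

[Term]
id: HP:0012824
name: Severity
is_a: HP:0012823 ! Clinical modifier

[Term]
id: HP:0012828
name: Severe
is_a: HP:0012824 ! Severity

[Term]
id: HP:0031797
name: Clinical course
is_a: HP:0000001 ! All

[Term]
id: HP:0003674
name: Onset
is_a: HP:0031797 ! Clinical course

[Term]
id: HP:0003623
name: Neonatal onset
is_a: HP:0003674 ! Onset

[Term]
id: HP:0000741
name: Obsolete apathy
is_obsolete: true
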