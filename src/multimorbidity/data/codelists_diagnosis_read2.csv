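code,condition_id
B011.,hypertension
B012.,hypertension
B013.,hypertension
C021.,anxiety_depression
C022.,anxiety_depression
C023.,anxiety_depression
D031.,hearing_loss
D032.,hearing_loss
D033.,hearing_loss
E041.,irritable_bowel_syndrome
E042.,irritable_bowel_syndrome
E043.,irritable_bowel_syndrome
F051.,asthma
F052.,asthma
F053.,asthma
G061.,diabetes
G062.,diabetes
G063.,diabetes
H071.,coronary_heart_disease
H072.,coronary_heart_disease
H073.,coronary_heart_disease
J091.,thyroid_disorder
J092.,thyroid_disorder
J093.,thyroid_disorder
K101.,cancer
K102.,cancer
K103.,cancer
L111.,atrial_fibrillation
L112.,atrial_fibrillation
L113.,atrial_fibrillation
N131.,stroke_tia
N132.,stroke_tia
N133.,stroke_tia
O141.,copd
O142.,copd
O143.,copd
P151.,connective_tissue_disorder
P152.,connective_tissue_disorder
P153.,connective_tissue_disorder
Q161.,diverticular_disease
Q162.,diverticular_disease
Q163.,diverticular_disease
R171.,heart_failure
R172.,heart_failure
R173.,heart_failure
S181.,dementia
S182.,dementia
S183.,dementia
T191.,epilepsy
T192.,epilepsy
T193.,epilepsy
U201.,schizophrenia_bipolar
U202.,schizophrenia_bipolar
U203.,schizophrenia_bipolar
V211.,psoriasis_eczema
V212.,psoriasis_eczema
V213.,psoriasis_eczema
W221.,inflammatory_bowel_disease
W222.,inflammatory_bowel_disease
W223.,inflammatory_bowel_disease
Y241.,blindness
Y242.,blindness
Y243.,blindness
Z251.,peripheral_vascular_disease
Z252.,peripheral_vascular_disease
Z253.,peripheral_vascular_disease
A261.,parkinsons
A262.,parkinsons
A263.,parkinsons
B271.,anorexia_bulimia
B272.,anorexia_bulimia
B273.,anorexia_bulimia
C281.,alcohol_problem
C282.,alcohol_problem
C283.,alcohol_problem
D291.,substance_misuse
D292.,substance_misuse
D293.,substance_misuse
E301.,chronic_liver_disease
E302.,chronic_liver_disease
E303.,chronic_liver_disease
F311.,prostate_disorder
F312.,prostate_disorder
F313.,prostate_disorder
G321.,glaucoma
G322.,glaucoma
G323.,glaucoma
H331.,learning_disability
H332.,learning_disability
H333.,learning_disability
I341.,multiple_sclerosis
I342.,multiple_sclerosis
I343.,multiple_sclerosis
J351.,bronchiectasis
J352.,bronchiectasis
J353.,bronchiectasis
K361.,chronic_sinusitis
K362.,chronic_sinusitis
K363.,chronic_sinusitis
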