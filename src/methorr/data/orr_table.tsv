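cancer_code	orr	tumor_type
ACC	0.06	Adrenocortical carcinoma
BLCA	0.182	Bladder urothelial carcinoma
BRCA	0.052	Breast invasive carcinoma
CESC	0.208	Cervical squamous cell carcinoma and endocervical adenocarcinoma
ESCA	0.112	Esophageal carcinoma
GBM	0.08	Glioblastoma multiforme
HNSC	0.16	Head and neck squamous cell carcinoma
KIRC	0.25	Kidney renal clear cell carcinoma
LIHC	0.2	Liver hepatocellular carcinoma
LUAD	0.19	Lung adenocarcinoma
LUSC	0.2	Lung squamous cell carcinoma
MESO	0.167	Mesothelioma
OV	0.097	Ovarian serous cystadenocarcinoma
PAAD	0	Pancreatic adenocarcinoma
SARC	0.11	Sarcoma
SKCM	0.387	Skin cutaneous melanoma
UCEC	0.13	Uterine corpus endometrial carcinoma
UVM	0.036	Uveal melanoma
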