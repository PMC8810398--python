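# Default underlying-cause codelist: ONS drug-poisoning definition plus
# conventional ICD-10 chapter/block prefixes. Replaceable data, not code.
icd10_prefix,group,subgroup,exclusive_label
F11,drug_poisoning,,drug_poisoning
F12,drug_poisoning,,drug_poisoning
F13,drug_poisoning,,drug_poisoning
F14,drug_poisoning,,drug_poisoning
F15,drug_poisoning,,drug_poisoning
F16,drug_poisoning,,drug_poisoning
F18,drug_poisoning,,drug_poisoning
F19,drug_poisoning,,drug_poisoning
X40,drug_poisoning,,drug_poisoning
X41,drug_poisoning,,drug_poisoning
X42,drug_poisoning,,drug_poisoning
X43,drug_poisoning,,drug_poisoning
X44,drug_poisoning,,drug_poisoning
X60,drug_poisoning,,drug_poisoning
X61,drug_poisoning,,drug_poisoning
X62,drug_poisoning,,drug_poisoning
X63,drug_poisoning,,drug_poisoning
X64,drug_poisoning,,drug_poisoning
X85,drug_poisoning,,drug_poisoning
Y10,drug_poisoning,,drug_poisoning
Y11,drug_poisoning,,drug_poisoning
Y12,drug_poisoning,,drug_poisoning
Y13,drug_poisoning,,drug_poisoning
Y14,drug_poisoning,,drug_poisoning
A,infections,,
B,infections,,
B15,infections,viral_hepatitis,
B16,infections,viral_hepatitis,
B17,infections,viral_hepatitis,
B18,infections,viral_hepatitis,
B19,infections,viral_hepatitis,
B20,infections,hiv,
B21,infections,hiv,
B22,infections,hiv,
B23,infections,hiv,
B24,infections,hiv,
C,cancers,,other_cancer
C15,cancers,digestive,other_cancer
C16,cancers,digestive,other_cancer
C17,cancers,digestive,other_cancer
C18,cancers,digestive,other_cancer
C19,cancers,digestive,other_cancer
C20,cancers,digestive,other_cancer
C21,cancers,digestive,other_cancer
C22,cancers,digestive,other_cancer
C23,cancers,digestive,other_cancer
C24,cancers,digestive,other_cancer
C25,cancers,digestive,other_cancer
C26,cancers,digestive,other_cancer
C30,cancers,respiratory,respiratory_cancer
C31,cancers,respiratory,respiratory_cancer
C32,cancers,respiratory,respiratory_cancer
C33,cancers,respiratory,respiratory_cancer
C34,cancers,respiratory,respiratory_cancer
C35,cancers,respiratory,respiratory_cancer
C36,cancers,respiratory,respiratory_cancer
C37,cancers,respiratory,respiratory_cancer
C38,cancers,respiratory,respiratory_cancer
C39,cancers,respiratory,respiratory_cancer
C50,cancers,breast,other_cancer
C51,cancers,female_genital,other_cancer
C52,cancers,female_genital,other_cancer
C53,cancers,female_genital,other_cancer
C54,cancers,female_genital,other_cancer
C55,cancers,female_genital,other_cancer
C56,cancers,female_genital,other_cancer
C57,cancers,female_genital,other_cancer
C58,cancers,female_genital,other_cancer
C81,cancers,lymphoid_haematopoietic,other_cancer
C82,cancers,lymphoid_haematopoietic,other_cancer
C83,cancers,lymphoid_haematopoietic,other_cancer
C84,cancers,lymphoid_haematopoietic,other_cancer
C85,cancers,lymphoid_haematopoietic,other_cancer
C86,cancers,lymphoid_haematopoietic,other_cancer
C87,cancers,lymphoid_haematopoietic,other_cancer
C88,cancers,lymphoid_haematopoietic,other_cancer
C89,cancers,lymphoid_haematopoietic,other_cancer
C90,cancers,lymphoid_haematopoietic,other_cancer
C91,cancers,lymphoid_haematopoietic,other_cancer
C92,cancers,lymphoid_haematopoietic,other_cancer
C93,cancers,lymphoid_haematopoietic,other_cancer
C94,cancers,lymphoid_haematopoietic,other_cancer
C95,cancers,lymphoid_haematopoietic,other_cancer
C96,cancers,lymphoid_haematopoietic,other_cancer
G,nervous_system,,
I,circulatory,,circulatory
I20,circulatory,ischaemic_heart_disease,circulatory
I21,circulatory,ischaemic_heart_disease,circulatory
I22,circulatory,ischaemic_heart_disease,circulatory
I23,circulatory,ischaemic_heart_disease,circulatory
I24,circulatory,ischaemic_heart_disease,circulatory
I25,circulatory,ischaemic_heart_disease,circulatory
I60,circulatory,cerebrovascular,circulatory
I61,circulatory,cerebrovascular,circulatory
I62,circulatory,cerebrovascular,circulatory
I63,circulatory,cerebrovascular,circulatory
I64,circulatory,cerebrovascular,circulatory
I65,circulatory,cerebrovascular,circulatory
I66,circulatory,cerebrovascular,circulatory
I67,circulatory,cerebrovascular,circulatory
I68,circulatory,cerebrovascular,circulatory
I69,circulatory,cerebrovascular,circulatory
J,respiratory,,other_respiratory
J09,respiratory,influenza_pneumonia,other_respiratory
J10,respiratory,influenza_pneumonia,other_respiratory
J11,respiratory,influenza_pneumonia,other_respiratory
J12,respiratory,influenza_pneumonia,other_respiratory
J13,respiratory,influenza_pneumonia,other_respiratory
J14,respiratory,influenza_pneumonia,other_respiratory
J15,respiratory,influenza_pneumonia,other_respiratory
J16,respiratory,influenza_pneumonia,other_respiratory
J17,respiratory,influenza_pneumonia,other_respiratory
J18,respiratory,influenza_pneumonia,other_respiratory
J40,respiratory,copd,copd
J41,respiratory,copd,copd
J42,respiratory,copd,copd
J43,respiratory,copd,copd
J44,respiratory,copd,copd
K,digestive,,
K70,digestive,liver,liver
K71,digestive,liver,liver
K72,digestive,liver,liver
K73,digestive,liver,liver
K74,digestive,liver,liver
K75,digestive,liver,liver
K76,digestive,liver,liver
K77,digestive,liver,liver
V,external,accidents,external
W,external,accidents,external
X,external,accidents,external
X60,external,suicide,external
X61,external,suicide,external
X62,external,suicide,external
X63,external,suicide,external
X64,external,suicide,external
X65,external,suicide,external
X66,external,suicide,external
X67,external,suicide,external
X68,external,suicide,external
X69,external,suicide,external
X70,external,suicide,external
X71,external,suicide,external
X72,external,suicide,external
X73,external,suicide,external
X74,external,suicide,external
X75,external,suicide,external
X76,external,suicide,external
X77,external,suicide,external
X78,external,suicide,external
X79,external,suicide,external
X80,external,suicide,external
X81,external,suicide,external
X82,external,suicide,external
X83,external,suicide,external
X84,external,suicide,external
X85,external,,external
X86,external,,external
X87,external,,external
X88,external,,external
X89,external,,external
X90,external,,external
X91,external,,external
X92,external,,external
X93,external,,external
X94,external,,external
X95,external,,external
X96,external,,external
X97,external,,external
X98,external,,external
X99,external,,external
Y,external,,external
Y20,external,suicide,external
Y21,external,suicide,external
Y22,external,suicide,external
Y23,external,suicide,external
Y24,external,suicide,external
Y25,external,suicide,external
Y26,external,suicide,external
Y27,external,suicide,external
Y28,external,suicide,external
Y29,external,suicide,external
Y30,external,suicide,external
Y31,external,suicide,external
Y32,external,suicide,external
Y33,external,suicide,external
Y34,external,suicide,external
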