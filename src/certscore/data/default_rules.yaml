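# Default rule configuration for death-certificate error detection.
#
# All terms are matched on normalized text (lowercase, accents stripped,
# whitespace collapsed); Spanish clinical vocabulary with English aliases.
# The causal relation is a cause -> consequence graph over condition
# categories; sequence checking uses its transitive closure. Every list here
# can be overridden by loading a user file with the same structure.

ill_defined:
  - paro cardiaco
  - paro respiratorio
  - paro cardiorrespiratorio
  - insuficiencia cardiaca
  - insuficiencia hepatica
  - insuficiencia renal
  - insuficiencia respiratoria
  - falla organica multiple
  - falla multiorganica
  - shock
  - choque
  - choque septico
  - choque hipovolemico
  - hematemesis
  - disnea
  - fiebre
  - coma
  - senilidad
  - caquexia
  - resfriado comun
  - rinitis
  # English aliases
  - cardiac arrest
  - respiratory arrest
  - heart failure
  - hepatic failure
  - renal failure
  - respiratory failure
  - multiorgan failure
  - fever
  - dyspnoea
  - senility

abbreviations: [iam, acv, epoc, vih, tbc, erc, hta, dm, tep, uci, sdra, irc, evc, hda, copd, hiv, mi]

abbreviation_whitelist: [II, III, IV]

conjunctions: [";", ",", " y ", " con ", " and "]

# Exact normalized condition text -> category used by sequence checking.
category_map:
  diabetes mellitus tipo 2: diabetes
  hipertension arterial esencial: hypertension
  infarto agudo de miocardio: ischemic_heart_disease
  accidente cerebrovascular isquemico: cerebrovascular
  enfermedad renal cronica: chronic_kidney
  neumonia: pneumonia
  sepsis: sepsis
  tuberculosis pulmonar: tuberculosis
  infeccion por virus de inmunodeficiencia humana: hiv
  enfermedad pulmonar obstructiva cronica: copd
  cirrosis hepatica: cirrhosis
  hepatitis cronica: hepatitis
  neoplasia maligna de estomago: gastric_cancer
  neoplasia maligna de pulmon: lung_cancer
  peritonitis: peritonitis
  apendicitis aguda: appendicitis
  meningitis bacteriana: meningitis
  fractura de femur: fracture
  traumatismo: external_trauma
  paro cardiorrespiratorio: mode_of_dying

# cause -> consequence pairs (acyclic); closure taken transitively.
causal_pairs:
  - [diabetes, chronic_kidney]
  - [diabetes, ischemic_heart_disease]
  - [diabetes, cerebrovascular]
  - [diabetes, sepsis]
  - [hypertension, ischemic_heart_disease]
  - [hypertension, cerebrovascular]
  - [hypertension, chronic_kidney]
  - [pneumonia, sepsis]
  - [tuberculosis, pneumonia]
  - [hiv, tuberculosis]
  - [hiv, pneumonia]
  - [hiv, sepsis]
  - [copd, pneumonia]
  - [hepatitis, cirrhosis]
  - [cirrhosis, sepsis]
  - [cirrhosis, peritonitis]
  - [gastric_cancer, sepsis]
  - [lung_cancer, pneumonia]
  - [lung_cancer, sepsis]
  - [appendicitis, peritonitis]
  - [peritonitis, sepsis]
  - [meningitis, sepsis]
  - [fracture, sepsis]
  - [external_trauma, fracture]
  - [external_trauma, sepsis]

# Categories that cannot initiate a chain of events (invalid as UCOD).
non_initiating: [mode_of_dying]

neoplasm_terms: [neoplasia, tumor, cancer, carcinoma]
neoplasm_qualifiers:
  - maligna
  - maligno
  - benigna
  - benigno
  - metastasico
  - metastasica
  - estomago
  - pulmon
  - mama
  - colon
  - prostata
  - higado
  - pancreas
  - gastrico
  - cerebral

external_terms: [traumatismo, envenenamiento, ahogamiento, quemadura]
external_intent_terms: [accidental, no intencional, autoinfligido, agresion, suicidio, homicidio]
external_mechanism_terms: [caida, altura, transito, vehiculo, fuego, gas, inmersion, arma de fuego, objeto punzocortante]

hypertension_terms: [hipertension]
hypertension_qualifiers: [esencial, primaria, secundaria]

diabetes_terms: [diabetes]
diabetes_qualifiers: [tipo 1, tipo 2, tipo i, tipo ii, gestacional]

ucod_capable_terms:
  - tuberculosis pulmonar
  - neumonia
  - infarto agudo de miocardio
  - neoplasia maligna de estomago
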