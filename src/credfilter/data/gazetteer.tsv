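Pfizer	ORGANIZATION
Moderna	ORGANIZATION
AstraZeneca	ORGANIZATION
Novartis	ORGANIZATION
Bayer	ORGANIZATION
WHO	ORGANIZATION
CDC	ORGANIZATION
FDA	ORGANIZATION
NIH	ORGANIZATION
NHS	ORGANIZATION
Cochrane	ORGANIZATION
Lancet	ORGANIZATION
Harvard	ORGANIZATION
Mayo Clinic	ORGANIZATION
Big Pharma	ORGANIZATION
Tylenol	PRODUCT
Advil	PRODUCT
Lipitor	PRODUCT
Prozac	PRODUCT
Xanax	PRODUCT
Ritalin	PRODUCT
Gardasil	PRODUCT
Feingold	PERSON
Wakefield	PERSON
Fauci	PERSON
Mercola	PERSON
Pasteur	PERSON
Salk	PERSON
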