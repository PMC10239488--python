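# 10-species rodent/bat cohort: maximum lifespans (years) for the four rodents
# and M. molossus as printed in the study text; the five remaining bat
# lifespans from the AnAge database. Assembly sizes (Gb) from the per-order
# content tables; body masses are approximate adult values (descriptive only).
species	lifespan_years	mass_g	assembly_gb	phenotype
Heterocephalus_glaber	31	35	3.042	long_lived_cancer_resistant
Cavia_porcellus	12	728	2.723	short_lived_cancer_prone
Mus_musculus	4	20.5	2.728	short_lived_cancer_prone
Rattus_norvegicus	3.8	300	2.648	short_lived_cancer_prone
Myotis_myotis	37.1	28	2.003	long_lived_cancer_resistant
Myotis_lucifugus	34	14	2.035	long_lived_cancer_resistant
Rhinolophus_ferrumequinum	30.5	23	2.075	long_lived_cancer_resistant
Rousettus_aegyptiacus	22.9	146	1.893	long_lived_cancer_resistant
Pteropus_vampyrus	20.9	1100	1.996	long_lived_cancer_resistant
Molossus_molossus	5.6	12	2.319	short_lived_cancer_resistant
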