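mutation	onset_age	onset_categories	major_features	minor_features
p.Arg104Gln		asymptomatic
p.Arg104Trp	1-10	early;classical	pyramidal_signs;optic_atrophy;mental_retardation	other_minor
p.Gly127Asp	16	classical	pyramidal_signs
p.Gly127Val	6-62	late;classical
p.His165Arg	6-16	classical	subcortical_mri_lesions	sensorineural_hearing_loss
p.His165Asp	4-20	classical;early	pyramidal_signs
p.His165Leu	14	classical
p.His165Tyr	12	classical
p.Asp210Val	1.5	early	pyramidal_signs;optic_atrophy	cerebellar_ataxia;hearing_impairment;cataracts;learning_difficulties;mitochondrial_myopathy
p.Asp210Tyr	0.5	early	pyramidal_signs;optic_atrophy;mental_retardation	microcephaly;tremor;sensorineural_hearing_loss
p.Val244Leu	4	early		periventricular_leukomalacia
p.Val244Met	<5	early
p.Arg250Gln	12-21	late;classical
p.Arg250Trp	4-10	classical;early
p.Pro251Ala	8-50	classical		tremor
p.Pro251Arg	1-2	early	wheelchair_bound
p.Pro251Leu	25	late
p.Arg259Cys	>30	late	sudden_visual_loss
p.Arg259Leu	19	classical	mild_pyramidal_signs
p.Arg259His	17	classical
p.Arg274Gln	11-35	classical
p.Arg274Trp	10	classical	mental_retardation	reduced_motor_ncv;proximal_weakness
p.Gln276Arg	10	classical	optic_atrophy
p.Gln276His	9	classical	optic_atrophy
p.His277Arg	<15	classical
p.His277Tyr	<10	classical	pyramidal_signs	vasomotor_troubles
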