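# fixture brain region dictionary: name	acronyms	synonyms
# small synthetic stand-in for a full literature-compiled region dictionary;
# covers the regions used by the documentation examples and fixture corpora
Paraventricular nucleus of the thalamus	PVT	paraventricular thalamus, paraventricular thalamic nucleus
Anterior paraventricular nucleus of the thalamus	aPVT	anterior PVT
Posterior paraventricular nucleus of the thalamus	pPVT	posterior PVT
Pa	-	-
Pt	-	-
Amygdala	AMG	amygdaloid complex
Basal amygdala	-	basal amygdaloid nucleus
Central nucleus of the amygdala	CE	central amygdaloid nucleus
Hippocampus	-	hippocampal formation
Thalamus	-	-
Midline thalamus	-	-
Dorsal midline thalamus	-	-
Suprachiasmatic nucleus	SCN	suprachiasmatic nuclei
Nucleus accumbens	NAS, NAcc	accumbens nucleus
Prefrontal cortex	PFC	-
Medial prefrontal cortex	mPFC	-
Ventral subiculum	-	-
Hypothalamic orexin neurons	-	lateral hypothalamic orexin neurons
Hypothalamus	-	-
Lateral septum	-	-
Locus coeruleus	LC	-
Parabrachial nucleus	-	parabrachial nuclei
External lateral parabrachial subnucleus	-	-
Bed nucleus of the stria terminalis	BNST	-
Dorsal raphe	DR	caudal dorsal raphe
Infralimbic cortex	IL	-
Prelimbic cortex	PrL	-
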