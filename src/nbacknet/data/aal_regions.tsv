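name	abbreviation	hemisphere	lobe	group
Precentral gyrus	PreCG.L	L	Frontal	cortical
Precentral gyrus	PreCG.R	R	Frontal	cortical
Superior frontal gyrus, dorsolateral	SFGdor.L	L	Frontal	cortical
Superior frontal gyrus, dorsolateral	SFGdor.R	R	Frontal	cortical
Superior frontal gyrus, orbital part	ORBsup.L	L	Frontal	cortical
Superior frontal gyrus, orbital part	ORBsup.R	R	Frontal	cortical
Middle frontal gyrus	MFG.L	L	Frontal	cortical
Middle frontal gyrus	MFG.R	R	Frontal	cortical
Middle frontal gyrus, orbital part	ORBmid.L	L	Frontal	cortical
Middle frontal gyrus, orbital part	ORBmid.R	R	Frontal	cortical
Inferior frontal gyrus, opercular part	IFGoperc.L	L	Frontal	cortical
Inferior frontal gyrus, opercular part	IFGoperc.R	R	Frontal	cortical
Inferior frontal gyrus, triangular part	IFGtriang.L	L	Frontal	cortical
Inferior frontal gyrus, triangular part	IFGtriang.R	R	Frontal	cortical
Inferior frontal gyrus, orbital part	ORBinf.L	L	Frontal	cortical
Inferior frontal gyrus, orbital part	ORBinf.R	R	Frontal	cortical
Rolandic operculum	ROL.L	L	Frontal	cortical
Rolandic operculum	ROL.R	R	Frontal	cortical
Supplementary motor area	SMA.L	L	Frontal	cortical
Supplementary motor area	SMA.R	R	Frontal	cortical
Olfactory cortex	OLF.L	L	Frontal	cortical
Olfactory cortex	OLF.R	R	Frontal	cortical
Superior frontal gyrus, medial	SFGmed.L	L	Frontal	cortical
Superior frontal gyrus, medial	SFGmed.R	R	Frontal	cortical
Superior frontal gyrus, medial orbital	ORBsupmed.L	L	Frontal	cortical
Superior frontal gyrus, medial orbital	ORBsupmed.R	R	Frontal	cortical
Gyrus rectus	REC.L	L	Frontal	cortical
Gyrus rectus	REC.R	R	Frontal	cortical
Insula	INS.L	L	Insula	cortical
Insula	INS.R	R	Insula	cortical
Anterior cingulate and paracingulate gyri	ACG.L	L	Limbic	cortical
Anterior cingulate and paracingulate gyri	ACG.R	R	Limbic	cortical
Median cingulate and paracingulate gyri	DCG.L	L	Limbic	cortical
Median cingulate and paracingulate gyri	DCG.R	R	Limbic	cortical
Posterior cingulate gyrus	PCG.L	L	Limbic	cortical
Posterior cingulate gyrus	PCG.R	R	Limbic	cortical
Hippocampus	HIP.L	L	Limbic	cortical
Hippocampus	HIP.R	R	Limbic	cortical
Parahippocampal gyrus	PHG.L	L	Limbic	cortical
Parahippocampal gyrus	PHG.R	R	Limbic	cortical
Amygdala	AMYG.L	L	Subcortical	subcortical
Amygdala	AMYG.R	R	Subcortical	subcortical
Calcarine fissure and surrounding cortex	CAL.L	L	Occipital	cortical
Calcarine fissure and surrounding cortex	CAL.R	R	Occipital	cortical
Cuneus	CUN.L	L	Occipital	cortical
Cuneus	CUN.R	R	Occipital	cortical
Lingual gyrus	LING.L	L	Occipital	cortical
Lingual gyrus	LING.R	R	Occipital	cortical
Superior occipital gyrus	SOG.L	L	Occipital	cortical
Superior occipital gyrus	SOG.R	R	Occipital	cortical
Middle occipital gyrus	MOG.L	L	Occipital	cortical
Middle occipital gyrus	MOG.R	R	Occipital	cortical
Inferior occipital gyrus	IOG.L	L	Occipital	cortical
Inferior occipital gyrus	IOG.R	R	Occipital	cortical
Fusiform gyrus	FFG.L	L	Occipital	cortical
Fusiform gyrus	FFG.R	R	Occipital	cortical
Postcentral gyrus	PoCG.L	L	Parietal	cortical
Postcentral gyrus	PoCG.R	R	Parietal	cortical
Superior parietal gyrus	SPG.L	L	Parietal	cortical
Superior parietal gyrus	SPG.R	R	Parietal	cortical
Inferior parietal gyrus	IPL.L	L	Parietal	cortical
Inferior parietal gyrus	IPL.R	R	Parietal	cortical
Supramarginal gyrus	SMG.L	L	Parietal	cortical
Supramarginal gyrus	SMG.R	R	Parietal	cortical
Angular gyrus	ANG.L	L	Parietal	cortical
Angular gyrus	ANG.R	R	Parietal	cortical
Precuneus	PCUN.L	L	Parietal	cortical
Precuneus	PCUN.R	R	Parietal	cortical
Paracentral lobule	PCL.L	L	Frontal	cortical
Paracentral lobule	PCL.R	R	Frontal	cortical
Caudate nucleus	CAU.L	L	Subcortical	subcortical
Caudate nucleus	CAU.R	R	Subcortical	subcortical
Lenticular nucleus, putamen	PUT.L	L	Subcortical	subcortical
Lenticular nucleus, putamen	PUT.R	R	Subcortical	subcortical
Lenticular nucleus, pallidum	PAL.L	L	Subcortical	subcortical
Lenticular nucleus, pallidum	PAL.R	R	Subcortical	subcortical
Thalamus	THA.L	L	Subcortical	subcortical
Thalamus	THA.R	R	Subcortical	subcortical
Heschl gyrus	HES.L	L	Temporal	cortical
Heschl gyrus	HES.R	R	Temporal	cortical
Superior temporal gyrus	STG.L	L	Temporal	cortical
Superior temporal gyrus	STG.R	R	Temporal	cortical
Temporal pole: superior temporal gyrus	TPOsup.L	L	Temporal	cortical
Temporal pole: superior temporal gyrus	TPOsup.R	R	Temporal	cortical
Middle temporal gyrus	MTG.L	L	Temporal	cortical
Middle temporal gyrus	MTG.R	R	Temporal	cortical
Temporal pole: middle temporal gyrus	TPOmid.L	L	Temporal	cortical
Temporal pole: middle temporal gyrus	TPOmid.R	R	Temporal	cortical
Inferior temporal gyrus	ITG.L	L	Temporal	cortical
Inferior temporal gyrus	ITG.R	R	Temporal	cortical
Cerebellum crus I	CRBCrus1.L	L	Cerebellum	cerebellar
Cerebellum crus I	CRBCrus1.R	R	Cerebellum	cerebellar
Cerebellum crus II	CRBCrus2.L	L	Cerebellum	cerebellar
Cerebellum crus II	CRBCrus2.R	R	Cerebellum	cerebellar
Cerebellum lobule III	CRB3.L	L	Cerebellum	cerebellar
Cerebellum lobule III	CRB3.R	R	Cerebellum	cerebellar
Cerebellum lobule IV-V	CRB4_5.L	L	Cerebellum	cerebellar
Cerebellum lobule IV-V	CRB4_5.R	R	Cerebellum	cerebellar
Cerebellum lobule VI	CRB6.L	L	Cerebellum	cerebellar
Cerebellum lobule VI	CRB6.R	R	Cerebellum	cerebellar
Cerebellum lobule VIIb	CRB7b.L	L	Cerebellum	cerebellar
Cerebellum lobule VIIb	CRB7b.R	R	Cerebellum	cerebellar
Cerebellum lobule VIII	CRB8.L	L	Cerebellum	cerebellar
Cerebellum lobule VIII	CRB8.R	R	Cerebellum	cerebellar
Cerebellum lobule IX	CRB9.L	L	Cerebellum	cerebellar
Cerebellum lobule IX	CRB9.R	R	Cerebellum	cerebellar
Cerebellum lobule X	CRB10.L	L	Cerebellum	cerebellar
Cerebellum lobule X	CRB10.R	R	Cerebellum	cerebellar
Vermis lobules I-II	VER1_2	M	Cerebellum	cerebellar
Vermis lobule III	VER3	M	Cerebellum	cerebellar
Vermis lobules IV-V	VER4_5	M	Cerebellum	cerebellar
Vermis lobule VI	VER6	M	Cerebellum	cerebellar
Vermis lobule VII	VER7	M	Cerebellum	cerebellar
Vermis lobule VIII	VER8	M	Cerebellum	cerebellar
Vermis lobule IX	VER9	M	Cerebellum	cerebellar
Vermis lobule X	VER10	M	Cerebellum	cerebellar
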