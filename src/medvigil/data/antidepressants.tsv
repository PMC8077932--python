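# Antidepressant lexicon: 49 generic names with the four major drug
# families. Family labels are approximate nearest-major-family
# assignments (atypical serotonergic agents are grouped with SSRI,
# atypical noradrenergic/dopaminergic agents with SNRI). The brand-name
# column is a small illustrative subset and is NOT exhaustive; extend it
# with your own file for brand-level matching.
generic	brands	family
agomelatine	valdoxan	SSRI
amineptine	survector	tricyclic
amitriptyline	elavil|endep	tricyclic
amoxapine	asendin	tricyclic
bupropion	wellbutrin|zyban	SNRI
butriptyline	evadyne	tricyclic
citalopram	celexa|cipramil	SSRI
clomipramine	anafranil	tricyclic
desipramine	norpramin	tricyclic
desvenlafaxine	pristiq	SNRI
dibenzepin	noveril	tricyclic
dosulepin	prothiaden	tricyclic
doxepin	sinequan|silenor	tricyclic
duloxetine	cymbalta|irenka	SNRI
escitalopram	lexapro|cipralex	SSRI
etoperidone	axiomin	SSRI
fluoxetine	prozac|sarafem	SSRI
fluvoxamine	luvox|faverin	SSRI
hydroxynefazodone		SSRI
imipramine	tofranil	tricyclic
iprindole	prondol	tricyclic
levomilnacipran	fetzima	SNRI
lofepramine	gamanil	tricyclic
maprotiline	ludiomil	tetracyclic
mazindol	sanorex	SNRI
meta-chlorophenylpiperazine		SSRI
mianserin	tolvon	tetracyclic
mirtazapine	remeron	tetracyclic
nefazodone	serzone	SSRI
nisoxetine		SNRI
nomifensine	merital	SNRI
norclomipramine		tricyclic
northiaden		tricyclic
nortriptyline	pamelor|aventyl	tricyclic
opipramol	insidon	tricyclic
oxaprotiline		tetracyclic
paroxetine	paxil|seroxat	SSRI
protriptyline	vivactil	tricyclic
reboxetine	edronax	SNRI
sertraline	zoloft|lustral	SSRI
setiptiline	tecipul	tetracyclic
trazodone	desyrel|oleptro	SSRI
triazoledione		SSRI
trimipramine	surmontil	tricyclic
venlafaxine	effexor	SNRI
vilazodone	viibryd	SSRI
viloxazine	vivalan	SNRI
vortioxetine	trintellix|brintellix	SSRI
zimelidine	zelmid	SSRI
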