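raw_name	atc_code	display_name
desipramine	N06AA01	Desipramine
imipramine	N06AA02	Imipramine
imipramine oxide	N06AA03	Imipramine oxide
clomipramine	N06AA04	Clomipramine
opipramol	N06AA05	Opipramol
trimipramine	N06AA06	Trimipramine
lofepramine	N06AA07	Lofepramine
dibenzepin	N06AA08	Dibenzepin
amitriptyline	N06AA09	Amitriptyline
nortriptyline	N06AA10	Nortriptyline
protriptyline	N06AA11	Protriptyline
doxepin	N06AA12	Doxepin
iprindole	N06AA13	Iprindole
melitracen	N06AA14	Melitracen
butriptyline	N06AA15	Butriptyline
dosulepin	N06AA16	Dosulepin
amoxapine	N06AA17	Amoxapine
dimetacrine	N06AA18	Dimetacrine
amineptine	N06AA19	Amineptine
maprotiline	N06AA21	Maprotiline
quinupramine	N06AA23	Quinupramine
amitriptylinoxide	N06AA25	Amitriptylinoxide
zimeldine	N06AB02	Zimeldine
fluoxetine	N06AB03	Fluoxetine
citalopram	N06AB04	Citalopram
paroxetine	N06AB05	Paroxetine
sertraline	N06AB06	Sertraline
alaproclate	N06AB07	Alaproclate
fluvoxamine	N06AB08	Fluvoxamine
etoperidone	N06AB09	Etoperidone
escitalopram	N06AB10	Escitalopram
isocarboxazid	N06AF01	Isocarboxazid
nialamide	N06AF02	Nialamide
phenelzine	N06AF03	Phenelzine
tranylcypromine	N06AF04	Tranylcypromine
iproniazide	N06AF05	Iproniazide
iproclozide	N06AF06	Iproclozide
moclobemide	N06AG02	Moclobemide
toloxatone	N06AG03	Toloxatone
oxitriptan	N06AX01	Oxitriptan
tryptophan	N06AX02	Tryptophan
mianserin	N06AX03	Mianserin
nomifensine	N06AX04	Nomifensine
trazodone	N06AX05	Trazodone
nefazodone	N06AX06	Nefazodone
minaprine	N06AX07	Minaprine
bifemelane	N06AX08	Bifemelane
viloxazine	N06AX09	Viloxazine
oxaflozane	N06AX10	Oxaflozane
mirtazapine	N06AX11	Mirtazapine
bupropion	N06AX12	Bupropion
medifoxamine	N06AX13	Medifoxamine
tianeptine	N06AX14	Tianeptine
pivagabine	N06AX15	Pivagabine
venlafaxine	N06AX16	Venlafaxine
milnacipran	N06AX17	Milnacipran
reboxetine	N06AX18	Reboxetine
gepirone	N06AX19	Gepirone
duloxetine	N06AX21	Duloxetine
agomelatine	N06AX22	Agomelatine
desvenlafaxine	N06AX23	Desvenlafaxine
vilazodone	N06AX24	Vilazodone
vortioxetine	N06AX26	Vortioxetine
esketamine	N06AX27	Esketamine
levomilnacipran	N06AX28	Levomilnacipran
wellbutrin	N06AX12	Bupropion
zyban	N06AX12	Bupropion
bupropion hcl	N06AX12	Bupropion
prozac	N06AB03	Fluoxetine
zoloft	N06AB06	Sertraline
cymbalta	N06AX21	Duloxetine
effexor	N06AX16	Venlafaxine
remeron	N06AX11	Mirtazapine
celexa	N06AB04	Citalopram
lexapro	N06AB10	Escitalopram
paxil	N06AB05	Paroxetine
elavil	N06AA09	Amitriptyline
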