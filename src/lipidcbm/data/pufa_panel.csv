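metabolite,full_name,pathway,precursor,never_detected
6kPGF1a,6-keto-prostaglandin F1 alpha,COX,ARA,0
TxB2,thromboxane B2,COX,ARA,0
PGE2,prostaglandin E2,COX,ARA,0
8-isoPGA2,8-iso prostaglandin A2,non-enzymatic,ARA,0
PGE3,prostaglandin E3,COX,EPA,0
15d-PGJ2,15-deoxy-delta-12-14-prostaglandin J2,COX,ARA,0
PGD2,prostaglandin D2,COX,ARA,0
PGF2a,prostaglandin F2 alpha,COX,ARA,0
LxA4,lipoxin A4,LOX,ARA,0
LxB4,lipoxin B4,LOX,ARA,1
RvD1,resolvin D1,LOX,DHA,1
RvD2,resolvin D2,LOX,DHA,1
RvD5,resolvin D5,LOX,DHA,0
7-Mar1,7-maresin 1,LOX,DHA,0
LtB4,leukotriene B4,LOX,ARA,0
LtB5,leukotriene B5,LOX,EPA,1
PDx,protectin Dx,LOX,DHA,0
18-HEPE,18-hydroxyeicosapentaenoic acid,CYP450,EPA,0
5-6-DiHETE,5-6-dihydroxyeicosatetraenoic acid,LOX,EPA,1
9-HODE,9-hydroxyoctadecadienoic acid,LOX,LA,0
13-HODE,13-hydroxyoctadecadienoic acid,LOX,LA,0
15-HETE,15-hydroxyeicosatetraenoic acid,LOX,ARA,0
12-HETE,12-hydroxyeicosatetraenoic acid,LOX,ARA,0
8-HETE,8-hydroxyeicosatetraenoic acid,LOX,ARA,0
5-HETE,5-hydroxyeicosatetraenoic acid,LOX,ARA,0
17-HDoHE,17-hydroxydocosahexaenoic acid,LOX,DHA,0
14-HDoHE,14-hydroxydocosahexaenoic acid,LOX,DHA,0
14-15-EET,14-15-epoxyeicosatrienoic acid,CYP450,ARA,1
11-12-EET,11-12-epoxyeicosatrienoic acid,CYP450,ARA,1
8-9-EET,8-9-epoxyeicosatrienoic acid,CYP450,ARA,0
5-6-EET,5-6-epoxyeicosatrienoic acid,CYP450,ARA,0
5-oxoETE,5-oxoeicosatetraenoic acid,LOX,ARA,0
13oxoODE,13-oxo-octadecadienoic acid,LOX,LA,0
9oxoODE,9-oxo-octadecadienoic acid,LOX,LA,0
9-10-DiHOME,9-10-dihydroxy-12-octadecenoic acid,CYP450,LA,0
12-13-DiHOME,12-13-dihydroxy-12-octadecenoic acid,CYP450,LA,0
9-HOTrE,9-hydroxy-10-12-15-octadecatrienoic acid,LOX,ALA,0
13-HOTrE,13-hydroxy-9-11-15-octadecatrienoic acid,LOX,ALA,0
10-TriHOME,9-10-13-trihydroxy-11-octadecenoic acid,LOX,LA,0
12-TriHOME,9-12-13-trihydroxy-11E-octadecenoic acid,LOX,LA,0
C10-3OH,3-hydroxydecanoic acid,BOx,other,0
C12-3OH,3-hydroxydodecanoic acid,BOx,other,0
C14-3OH,3-hydroxytetradecanoic acid,BOx,other,0
C16-3OH,3-hydroxyhexadecanoate,BOx,other,0
C18-3OH,3-hydroxyoctadecanoic acid,BOx,other,0
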