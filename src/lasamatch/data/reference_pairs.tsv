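row_id	generic_name	local_proprietary	overseas_similar	overseas_generic	match_percent	risk
1	ACA	AXAR®	RAXAR	grepafloxacin		high
2	ACETAMINOPHEN	TINYPHEN®	SINIPHEN	Caffeine, Propyphenazone, Salicylamide	70	high
3	ACETAMINOPHEN/CAFFEINE/IBUPROFEN	RAHAFEN®	RAPIFEN	Alfentanil	78	high
4	ADULT COLD PREPARATION-5	FARALEX®	FARMALEX	Cefalexin	91	high
5	ADULT COLD PREPARATION-7	ZOCAMAX®	TOPAMAX	topiramate	67	high
6	ADULT COLD PREPARATION-4	EXACOLD®	DEXACOL	Dexamethasone	67	high
7	ADULT COLD	GRIPHEN®	PRIPHEN	Nandrolone	78	high
8	AMANTADINE HCL	AMMOREL®	AMIOREL	Bromhexine	89	high
9	AMLODIPINE/ATORVASTATIN	TENSOLIP®	TENSOLIV	chlordiazepoxide-clidinium	80	high
10	ARIPIPRAZOLE	SEROZOL®	SEROZIL	Cefprozil	89	high
11	ATORVASTATIN	ATOSTROL®	HALOSTROL	halobetasol propionate	80	high
12	AZATHIOPRINE	AZARAM®	AZACTAM	aztreonam	81	high
13	BECLOMETHASONE DIPROPIONATE	BECLORHIN®	BECLOTRIN	Betametasona +Clotrimazol+ Gentamicina	88	high
14	BUSERELIN ACETATE	CINNAFACT®	CINNAPAC	Cinnarizine	73	high
15	CALAMINE	CALAMEX®	CALMEX	Doxylamine	80	high
16	CALCIUM FOLINATE	ROFOLIN®	ROFOXIN	Ceftriaxone: (ceftriaxone sodium and dextrose	89	high
17	CEFIXIME	LOPRAX®	LOPROX	Ciclopirox	88	high
18	CEFTIZOXIME SODIUM	AFAZOX®	AFAZOL	naphazoline hydrochloride	75	high
19	CETIRIZINE 2HCl	CETRIKIM®	CETROTIDE	Cetrorelix	60	medium
20	CETIRIZINE/PSEUDOEPHEDRINE	CETADIN®	CEFADIN	Cephalexin	89	high
21	CIPROFLOXACIN HCL	CIPLEX®	IPLEX	mecasermin rinfabate	75	high
22	CITALOPRAM HBR	BIOXAL®	BIOXTRA	saliva substitutes topical	66	high
23	CLOBUTINOL HCL	TIDOCAUGH®	ETIDOCAINE	Etidocaine	55	medium
24	CLOPIDOGREL	DIPIX®	DEPIXOL	Flupentixol	71	high
25	CO TRIMOXAZOLE	DUCOTRI®	DUCORT	Deflazacort	72	high
26	COLCHICINE	MODACINE®	MODACIN	Ceftazidime pentahydrate	80	high
27	CONTRACEPTIVE HD	OVUSTOP-H®	ACUSTOP	Flurbiprofen	45	medium
28	DEFERASIROX	OSVERAL®	FEVERALL	Acetaminophen	67	high
29	DIAZEPAM	ZEPADIC®	ZEPATIER	elbasvir and grazoprevir	67	high
30	DICLOFENAC SODIUM	DICLEN®	DICLEGIS	doxylamine and pyridoxine	75	high
31	DIMETHICONE	DILICE®	DILOMINE	dicyclomine	69	high
32	DOMPERIDONE MALEATE	MOTIDON®	METADON	methadone	78	high
33	ESOMEPRAZOLE	MAXOPRAZOL®	MEDOPRAZOLE	Omeprazole	75	high
34	EXPECTORANT	COUFEX®	KEFLEX	Cephalexin	47	medium
35	EZETIMIBE	EZITAL®	EMITAL	Ondansetron	88	high
36	FEXOFENADINE	ALLEXAFEN®	ALEXAN	Cytarabine	61	medium
37	FURAZOLIDONE	FURABEN®	FURACIN	nitrofurazone	78	high
38	GALANTAMINE	ALZAMIN®	ALAMIN	PHENYLEPHRINE HCL/CHLORPHENIRAMINE MALEATE	83	high
39	GEMCITABINE (as HCL)	CHEMOGEM®	CHEMOFER	Folic Acid, Iron, Vitamin B12	70	high
40	GLATIRAMER ACETATE	OSVIMER®	OSIMERTINIB	osimertinib	78	high
41	GRANISETRON	GRATRIL®	GABITRIL	tiagabine HCl	78	high
42	HEPARIN SODIUM	CLOTIN®	CLOPINE	clozapine	75	high
43	HYDROXYPROGESTERONE CAPROATE	FEMOLIFE®	MEMOLIFE	Vitamins and minerals	80	high
44	IBUPROFEN	ACTOPIN®	ACTAPIN	Amlodipine	89	high
45	IMIPENEM+CILASTATIN	CILAVIL®	CILARIL	Cilazapril	89	high
46	INTERFERON ALFA-2B	PDFERON®	MYFERON	polysaccharide-iron	67	high
47	IOHEXOL	OPAQUESOL®	ELDOPAQUE	Hidroquinone	55	medium
48	ISOXSUPRINE HCL	ISUPRINE®	ISUDRINE	aluminum phosphate & magnesium oxide	90	high
49	LATANOPROST+TIMOLOL	COPROST®	CARBOPROST	carboprost	90	high
50	LETROZOLE	LETRAX®	LETROX	levothyroxine	88	high
51	LEVOFLOXACIN	TAVANEX®	TAVINEX	Ambroxol	89	high
52	LIDOCAINE	XYLEX®	XYLAREX	d-xylitol	79	high
53	LISINOPRIL	LISIREX®	LIPIREX	Atorvastatin	89	high
54	LOSARTAN POTASSIUM	CARDIOSAN®	CARDIOGEN	cardiogen	82	high
55	LOSARTAN/HYDROCHLOROTHIAZIDE	HYDROZAAR®	HYDROPANE	homatropine/hydrocodone	64	medium
56	MEBEVERINE	COLIBSAN®	COLISTIN	colistimethate sodium	77	high
57	MEDROXYPROGESTERONE ACETATE	DEPOGESTRONE®	DEPO-TESTOSTERONE	testosterone cypionate	70	high
58	MEDROXYPROGESTERONE ACETATE	PROVEDIC®	PROVENTIL	albuterol sulfate	67	high
59	MELOXICAM	ROMATOBIC®	CROMATONBIC	Calcium Folinate, Vitamin B12	83	high
60	METFORMIN HCL	METOVER®	MEROVER	meropenem	89	high
61	METHOCARBAMOL	RELAXIMOL®	RELAXOL	Citalopram	69	high
62	METOCLOPRAMIDE	PLADIC®	PLACIDYL	Ethchlorvynol	69	high
63	METOPROLOL TARTRATE	TEDAPROL®	TEDAROL	Triamcinolone Diacetate	82	high
64	MUPIROCIN	AFIROCIN®	AZITROCIN	azithromycin	85	high
65	NANDROLONE DECANOATE	DECANDROLONE®	OXANDROLONE	Oxandrolone	71	high
66	NAPHAZOLINE ANTAZOLINE	ANAPRIVIN®	ANAPRILIN	propranolol	91	high
67	NAPROXEN	NAPTIN®	NAFTIN	naftifine hydrochloride	88	high
68	NITROGLYCERIN SR	TRICONTIN®	TRICON	Fluconazole	73	high
69	OLANZAPINE	ZYPROBIOX®	PROBIOX	Ciprofloxacin	73	high
70	ORLISTAT	XENOLIP®	FENOLIP	fenofibrate	78	high
71	OXYTOCIN	OXYTIP®	OXYVIT	Retinol	66	high
72	PANTOPRAZOLE	PENTOMID®	PENTOXIL	pentoxifylline	70	high
73	PANTOPRAZOLE	PANTOSS®	PANTOSSE	Ethylmorphine	89	high
74	PENTOXIFYLLINE	PENTAFIL®	PENTACEL	pentacel	80	high
75	PHENYLEPHRINE	NEOPHRIN®	NEOPYRIN	Acetaminophen	90	high
76	POLYETHYLENGLYCOL	COLOLAX®	CODOLAX	chlorpheniramine maleate/codeine phosphate/papaverine hydrochloride	89	high
77	PRASUGREL	BIOSUGREL®	BIOSURE	Amikacin	68	high
78	PROPYLTHIOURACIL	PROURACIL®	FLUOROURACIL	Fluorouracil	82	high
79	QUETIAPINE	BIOQUETIN®	BIOQUIN	Hydroquinone	69	high
80	RALOXIFENE	RALOFEN®	TALOFEN	promazine hydrochloride	78	high
81	RANITIDINE	ARY-TAC®	ARATAC	amiodarone hydrochloride	78	high
82	RILUZOLE	RILONORM®	MILONORM	milonorm	80	high
83	RIVASTIGMINE	CHOLINUP®	CHOLINE	B vitamins	70	high
84	SOLIFENACIN	SOLIFEX®	SYLIFEX	Silymarin-phospholipides	89	high
85	SUCCINYLCHOLINE CHLORIDE	MIOKOLIN®	MONOLIN	isosorbide mononitrate	77	high
86	TADALAFIL	TIAGRIX®	TIARIX	Paroxetine	80	high
87	TAMSULOSIN	MODALUSIN®	MODAFINIL	Modafinil	57	medium
88	TESTOSTRONE ENANTATE	ANDRONE®	ANDROLONE	Nandrolone	84	high
89	THEOPHYLLINE	THEOMEX®	THEOMAX	ephedrine sulfate/hydroxyzine hydrochloride/theophylline	89	high
90	TIZANIDINE	SPALEX®	SALEX	Salicylic acid	84	high
91	TOPIRAMATE	CONVEX®	CONEX	dexbrompheniramine/pseudoephedrine	81	high
92	TRANEXAMIC ACID	TRANCID®	RANCID	Magnesium Hydroxide	78	high
93	TRIAMCINOLONE ACETONIDE	CORTIRAN®	CORTIRON	Desoxycortone	90	high
94	TRIPTORELIN ACETATE	MICRORELIN®	MICROGESTIN	ethinyl estradiol/norethindrone	79	high
95	VENLAFAXINE	DEPRILAX®	PERILAX	Eperisone	75	high
96	VITAMIN A	A-VIGEL®	DIVIGEL	estradiol gel/Hormone	75	high
97	VITAMIN B1/B6/B12	NOROBIT®	NORBIT	Norfloxacin	80	high
98	VITAMIN B12	VIBALMIN®	VISALMIN	chloramphenicol	90	high
99	ZOLPIDEM	RAPIDEM®	RAPIDE	diclofenac potassium	78	high
100	ZONISAMIDE	ZONITED®	ZONITE	Thymol/Propylene Glycol/Benzalkonium/Edetic Acid/Sodium Acetate/Menthol	78	high
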