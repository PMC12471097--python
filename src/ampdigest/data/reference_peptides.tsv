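no	apd_id	name	source	sequence
1	AP00236	Pyrularia thionin	Nuts, Pyrularia pubera	KSCCRNTWARNCYNVCRLPGTISREICAKKCDCKIISGTTCPSDYPK
2	AP00532	Lunatusin	Lima bean Phaseolus lunatus L.	KTCENLADTFRGPCFATSNC
3	AP00553	Sesquin	Ground bean seeds, Vigna sesquipedalis	KTCENLADTY
4	AP00984	TPP3	Tomato, Lycopersicon esculentum	QICKAPSQTFPGLCFMDSSCRKYCIKEKFTGGHCSKLQRKCLCTKPC
5	AP00979	NaD1	ornamental tobacco flowers, Nicotiana alata	RECKTESNTFPGICITKPPCRKACISEKFTDGHCSKILRRCLCTKPC
6	AP01026	Varv peptide A	Viola arvensis, Viola odorata, Viola tricolor, Viola baoshanensi, Viola yedoensis, and Viola biflora	GLPVCGETCVGGTCNTPGCSCSWPVCTRN
7	AP01031	Varv peptide F	Viola arvensis	GVPICGETCTLGTCYTAGCSCSWPVCTRN
8	AP01036	Cycloviolacin O2	Viola odorata	GIPCGESCVWIPCISSAIGCSCKSKVCYRN
9	AP01121	Vibi E	Alpine violet Viola biflora	GIPCAESCVWIPCTVTALIGCGCSNKVCYN
10	AP01123	Vibi G	Alpine violet Viola biflora	GTFPCGESCVFIPCLTSAIGCSCKSKVCYKN
11	AP01124	Vibi H	Alpine violet Viola biflora	GLLPCAESCVYIPCLTTVIGCSCKSKVCYKN
12	AP01277	Viscotoxin A3	The European mistletoe, Viscum album L.	KSCCPNTTGRNIYNACRLTGAPRPTCAKLSGCKIISGSTCPSDYPK
13	AP01278	Viscotoxin 1-Ps	The European mistletoe, Viscum album L.	KSCCPNTTGRNIYNTCRFGGGSREVCARISGCKIISASTCPSDYPK
14	AP01279	Viscotoxin A1	Viscum album L. seeds	KSCCPNTTGRNIYNTCRLTGSSRETCAKLSGCKIISASTCPSNYPK
15	AP01280	Viscotoxin C	The Asiatic Viscum album ssp. Coloratum ohwi	KSCCPNTTGRNIYNTCRFAGGSRERCAKLSGCKIISASTCPSDYPK
16	AP01281	Viscotoxin A2	Viscum album L.	KSCCPNTTGRNIYNTCRFGGGSRQVCASLSGCKIISASTCPSDYPK
17	AP01282	Viscotoxin B	Viscum album L.	KSCCPNTTGRNIYNTCRLGGGSRERCASLSGCKIISASTCPSDYPK
18	AP01284	Viscotoxin B2	Viscum coloratum (Kom.) Nakai	KSCCKNTTGRNIYNTCRFAGGSRERCAKLSGCKIISASTCPSDYPK
19	AP01342	Cn-AMP1	Green coconut water, Cocos nucifera	SVAGRAQGM
20	AP01343	Cn-AMP2	Green coconut water, Cocos nucife	TESYFVFSVGM
21	AP01774	Cliotide T1	Clitoria ternatea	GIPCGESCVFIPCITGAIGCSCKSKVCYRN
22	AP01775	Cliotide T2	Clitoria ternatea	GEFLKCGESCVQGECYTPGCSCDWPICKKN
23	AP01776	Cliotide T3	Clitoria ternatea	GLPTCGETCTLGTCYVPDCSCSWPICMKN
24	AP01777	Cliotide T4	Clitoria ternatea	GIPCGESCVFIPCITAAIGCSCKSKVCYRN
25	AP01784	Vaby A	Africa, the Ethiopian highlands, Viola abyssinica	GLPVCGETCAGGTCNTPGCSCSWPICTRN
26	AP01785	Vaby D	Africa, the Ethiopian highlands, Viola abyssinica	GLPVCGETCFGGTCNTPGCTCDPWPVCTRN
27	AP01805	Cr-ACP1	Seeds, Cycas revoluta	AWKLFDDGV
28	AP01806	Viba 15	Viola philippica	GLPVCGETCVGGTCNTPGCACSWPVCTRN
29	AP01807	Viba17	Viola philippica	GLPVCGETCVGGTCNTPGCGCSWPVCTRN
30	AP01808	Viphi A	Viola philippica	GSIPCGESCVFIPCISSVIGCACKSKVCYKN
31	AP01809	Viphi D	Viola philippica	GIPCGESCVFIPCISSVIGCSCSSKVCYRN
32	AP01810	Viphi E	Viola philippica	GSIPCGESCVFIPCISAVIGCSCSNKVCYKN
33	AP01811	Viphi F	Viola philippica	GSIPCGESCVFIPCISAIIGCSCSSKVCYKN
34	AP01812	Viphi G	Viola philippica	GSIPCEGSCVFIPCISAIIGCSCSNKVCYKN
35	AP01813	Mram 8	Viola philippica	GIPCGESCVFIPCLTSAIDCSCKSKVCYRN
36	AP01983	Psyle A	Psychotria leptothyrsa	GIACGESCVFLGCFIPGCSCKSKVCYFN
37	AP01984	Psyle E	Psychotria leptothyrsa	GVIPCGESCVFIPCISSVLGCSCKNKVCYRD
38	AP01985	Psyle C	Psychotria leptothyrsa	KLCGETCFKFKCYTPGCSCSYPFCK
39	AP01986	ChaC1	Hybrid peptide of melittin and protamine	GDACGETCFTGICFTAGCSCNPWPTCTRN
40	AP01987	ChaC2	Chassalia chartacea	GIPCAESCVWIPPCTITALMGCSCKNNVCYNN
41	AP01988	ChaC4	Chassalia chartacea	GASCGETCFTGICFTAGCSCNPWPTCTRN
42	AP01989	ChaC7	Chassalia chartacea	IPCGESCVWIPCITAIAGCSCKNKVCYT
43	AP01990	ChaC8	Chassalia chartacea	AIPCGESCVWIPCISTVIGCSCSNKVCYR
44	AP01991	ChaC10	Chassalia chartacea	GEYCGESCYLIPCFTPGCYCVSRQCVNKN
45	AP01992	ChaC11	Chassalia chartacea	IPCGESCVWIPCISGMFGCSCKDKVCYS
46	AP02325	Cliotide T7	Clitoria ternatea	GIPCGESCVFIPCTVTALLGCSCKDKVCYKN
47	AP02326	Cliotide T10	Clitoria ternatea	GVPCAESCVWIPCTVTALLGCSCKDKVCYLN
48	AP02327	Cliotide T12	Clitoria ternatea	GIPCGESCVYIPCTVTALLGCSCKDKVCYKN
49	AP02328	Cliotide T19	Clitoria ternatea	GSVIKCGESCLLGKCYTPGCTCSRPICKKD
50	AP02329	Lunasin	Glycine max	SKWQHQQDSCRKQLQGVNLTPCEKHIMEKIQGRGDDDDDDDDD
51	AP02332	PaDef	Avocado fruit, Persea americana var. drymifolia	CETPSKHFNGLCIRSSNCASVCHGEHFTDGRCQGVRRRCMCLKPC
52	AP02340	Cyclosaplin	Somatic seedlings, Santalum album L.	RLGDGCTR
53	AP02657	Vigno 5	Viola ignobilis	GLPLCGETCVGGTCNTPGCSCGWPVCVRN
54	AP02659	DC1	Hedyotis diffusa	GAFLKCGESCVYLPCLTTVVGCSCQNSVCYRD
55	AP02660	DC2	Hedyotis diffusa	GAVPCGETCVYLPCITPDIGCSCQNKVCYRD
56	AP02661	DC3	Hedyotis diffusa	GTSCGETCVLLPCLSSVLGCTCQNKRCYKD
57	AP05050	Hyen D	Hybanthus enneaspermus	GFPCGESCVYIPCFTAAIGCSCKSKVCYKN
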