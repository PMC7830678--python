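herb	compound
DG	Beta-sitosterol
DG	stigmasterol
DG	senkyunolide A
DG	senkyunolide G
DG	senkyunolide I
DG	senkyunolide J
DG	ferulic acid
DG	vanillin
DG	Z-6,8′,7,3′-diligustilide
DG	ferulaldehyde
DG	Z-ligustilide
GZ	(+)-catechin
GZ	ent-epicatechin
GZ	(−)-taxifolin
GZ	cinnamaldehyde
GZ	cinnamic alcohol
GZ	O-methoxycinnamaldehyde
GZ	cinnamic acid
GZ	D-camphene
GZ	()-Terpinen-4-ol
GZ	benzaldehyde
SY	Paeoniflorgenone
SY	albiflorin_qt
SY	paeoniflorin
SY	lactiflorin
SY	benzoyl paeoniflorin
SY	kaempferol
SY	mairin
SY	(3S,5R,8R,9R,10S,14S)-3,17-dihydroxy-4,4,8,10,14-pentamethyl-2,3,5,6,7,9-hexahydro-1H-cyclopenta[a]phenanthrene-15,16-dione
SY	paeonol
SY	oxypaeoniflorin
SY	gallotannin
SY	albiflorin
XX	Cryptopin
XX	zinc05223929
XX	sesamin
XX	caribine
XX	methyleugenol
XX	α-pinene
XX	safrol
XX	asarone
GC	Glabrene
GC	glabridin
GC	glycyrol
GC	isoglycyrol
GC	licochalcone a
GC	liquiritigenin
GC	liquiritin
GC	18beta-glycyrrhetinic acid
GC	glycyrrhizin
GC	isoliquiritigenin
GC	isoliquiritin
TC	Paryriogenin A
TC	Paryriogenin I
TC	tetrapanoside B_qt
DZ	Stepharine
DZ	spiradine A
DZ	quercetin
DZ	(S)-coclaurine
DZ	coumestrol
DZ	fumarine
DZ	berberine
DZ	mauritine D
DZ	beta-carotene
DZ	nuciferin
DZ	zizyphus saponin I_qt
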