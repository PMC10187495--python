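Freude|NN	0.6502	Freuden
wichtig|ADJX	0.3822	wichtige,wichtigem,wichtigen,wichtiger,wichtiges
helfen|VVINF	0.3365	half,geholfen,hilft,helfe,halfen
Schutz|NN	0.2971	Schutzes,Schutze
aktuell|ADJX	0.0040	aktuelle,aktuellem,aktuellen,aktueller,aktuelles
gemeinsam|ADJX	0.3265	gemeinsame,gemeinsamem,gemeinsamen,gemeinsamer,gemeinsames
erklärt|ADJX	0.1230	erklärte,erklärtem,erklärten,erklärter,erklärtes
klar|ADJX	0.2971	klare,klarem,klaren,klarer,klares
schnell|ADJX	0.0771	schnelle,schnellem,schnellen,schneller,schnelles
Erfolg|NN	0.5034	Erfolge,Erfolgen,Erfolges
gut|ADJX	0.3716	gute,gutem,guten,guter,gutes
Hoffnung|NN	0.4877	Hoffnungen
sicher|ADJX	0.2263	sichere,sicherem,sicheren,sicherer,sicheres
Vertrauen|NN	0.3580	Vertrauens
stark|ADJX	0.1577	starke,starkem,starken,starker,starkes
Dank|NN	0.2960	Dankes,Danke
positiv|ADJX	0.2222	positive,positivem,positiven,positiver,positives
Verbesserung|NN	0.2939	Verbesserungen
Unterstützung|NN	0.3365	Unterstützungen
Mut|NN	0.2960	Mutes
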