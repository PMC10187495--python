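schädlich|ADJX	-0.9269	schädliche,schädlichem,schädlichen,schädlicher,schädliches
Risiko|NN	-0.5367	Risiken,Risikos
verlangsamen|VVINF	-0.2960	verlangsamt,verlangsamte,verlangsamten
vermeiden|VVINF	-0.3365	vermeidet,vermied,vermieden
Epidemie|NN	-0.4842	Epidemien
reduzieren|VVINF	-0.2960	reduziert,reduzierte,reduzierten
Kampf|NN	-0.5034	Kampfes,Kämpfe,Kämpfen
Gefahr|NN	-0.6922	Gefahren
Infektion|NN	-0.4446	Infektionen
leider|ADV	-0.3374
Krise|NN	-0.5034	Krisen
falsch|ADJX	-0.4463	falsche,falschem,falschen,falscher,falsches
sterben|VVINF	-0.7908	stirbt,starb,gestorben,sterbe
Angst|NN	-0.6016	Ängste,Ängsten
Tod|NN	-0.7912	Todes,Tode
Verlust|NN	-0.5034	Verluste,Verlusten
schlecht|ADJX	-0.7706	schlechte,schlechtem,schlechten,schlechter,schlechtes
Sorge|NN	-0.4463	Sorgen
kritisch|ADJX	-0.3374	kritische,kritischem,kritischen,kritischer,kritisches
Krankheit|NN	-0.4842	Krankheiten
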