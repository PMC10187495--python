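heute
morgen
Woche
Montag
Dienstag
Bericht
Zahlen
Daten
Bundesland
Stadt
Land
Menschen
Personen
Gruppe
Treffen
Termin
Uhr
Video
Seite
Thema
Frage
Antwort
Beispiel
Bereich
Region
Schule
Arbeit
Haus
Wetter
Wasser
Zug
Auto
Telefon
Brief
Papier
Tisch
Fenster
Garten
Baum
Buch
Musik
Bild
Karte
Zeit
Jahr
Monat
Stunde
Abend
Mittag
Runde
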