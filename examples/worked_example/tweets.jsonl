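{"id": "t01", "created_at": "2020-02-15T10:00:00+01:00", "author": "behoerde_01", "group": "authority", "text": "Das Risiko steigt, bitte Kontakte vermeiden. #Corona", "lang": "de", "is_retweet": false, "is_quote": false, "is_reply": false}
{"id": "t02", "created_at": "2020-03-01T09:30:00+01:00", "author": "expert_01", "group": "expert", "text": "Die Epidemie ist eine Gefahr, viele Menschen sterben. #Covid", "lang": "de", "is_retweet": false, "is_quote": false, "is_reply": false}
{"id": "t03", "created_at": "2020-03-22T23:30:00+01:00", "author": "behoerde_02", "group": "authority", "text": "Gemeinsam helfen wir, das ist wichtig. Corona", "lang": "de", "is_retweet": false, "is_quote": false, "is_reply": false}
{"id": "t04", "created_at": "2020-03-23T08:00:00+01:00", "author": "behoerde_01", "group": "authority", "text": "Aktuelle Zahlen zur Pandemie heute.", "lang": "de", "is_retweet": false, "is_quote": false, "is_reply": false}
{"id": "t05", "created_at": "2020-06-10T12:00:00+02:00", "author": "expert_02", "group": "expert", "text": "Leider ist die Krise nicht vorbei. #Corona", "lang": "de", "is_retweet": false, "is_quote": false, "is_reply": false}
{"id": "t06", "created_at": "2020-07-01T15:00:00+02:00", "author": "expert_01", "group": "expert", "text": "Schönes Wetter heute am See.", "lang": "de", "is_retweet": false, "is_quote": false, "is_reply": false}
{"id": "t07", "created_at": "2020-08-15T11:00:00+02:00", "author": "behoerde_03", "group": "authority", "text": "Wichtig: Abstand halten! #Corona", "lang": "de", "is_retweet": true, "is_quote": false, "is_reply": false}
{"id": "t08", "created_at": "2020-09-10T16:00:00+02:00", "author": "expert_03", "group": "expert", "text": "The pandemic continues. #Covid", "lang": "en", "is_retweet": false, "is_quote": false, "is_reply": false}
{"id": "t09", "created_at": "2020-10-28T09:00:00+01:00", "author": "behoerde_02", "group": "authority", "text": "Der Impfstoff gibt Hoffnung.", "lang": "de", "is_retweet": false, "is_quote": false, "is_reply": false}
{"id": "t10", "created_at": "2020-10-29T10:00:00+01:00", "author": "expert_02", "group": "expert", "text": "Die Infektionen steigen, das ist schädlich. Inzidenz hoch", "lang": "de", "is_retweet": false, "is_quote": false, "is_reply": false}
{"id": "t11", "created_at": "2021-01-10T14:00:00+01:00", "author": "expert_01", "group": "expert", "text": "Freude über den Impfstoff, ein Erfolg!", "lang": "de", "is_retweet": false, "is_quote": false, "is_reply": false}
{"id": "t12", "created_at": "2021-02-01T10:00:00+01:00", "author": "behoerde_01", "group": "authority", "text": "Corona Zahlen aktuell", "lang": "de", "is_retweet": false, "is_quote": false, "is_reply": false}
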