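C01p010030.1_BnaDAR
Glyma.01g000100.Wm82.a2.v1
Horvu_BARKE_1H01G000300.1
TraesCS3D02G273600
Vitvi18g12230
Honeycrisp_HAP1_v1.0.031896
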