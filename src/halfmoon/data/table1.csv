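site,ndvi_before,ndvi_after,rain_before,rain_after,ndvi_pct_diff_printed,rain_pct_diff_printed
Boussarague,0.202,0.262,347,383,29.7,10.3
Dan Goudao,0.224,0.339,348,392,51.3,12.6
Dan Gueza,0.259,0.388,310,331,49.8,6.7
Danja,0.254,0.375,407,410,47.6,0.7
Dargue,0.183,0.246,330,380,34.4,15.1
Djero,0.133,0.183,372,424,37.6,14.0
Doumana Ara,0.229,0.315,354,417,37.6,17.8
Elkokia,0.269,0.439,395,386,63.2,2.2
Gochiro,0.221,0.384,356,424,73.8,18.9
Gougouhema,0.140,0.198,274,312,41.4,14.0
Ichirnawa,0.244,0.361,388,428,48.0,10.3
Kafat,0.185,0.335,266,325,81.1,22.4
Karkara,0.244,0.348,336,352,42.6,4.9
Koona,0.257,0.390,359,422,51.8,17.5
Koumari,0.232,0.330,275,311,42.2,13.3
Mourney,0.207,0.372,360,409,79.7,13.6
Raffa,0.324,0.436,360,419,34.6,16.4
Satara,0.098,0.145,279,311,48.0,11.2
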