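window,region_name,count_vehicle,count_treatment,p_value
15-25,Reuniens nucleus,0,2,0.073
15-25,Ventral pallidum,0,3,0.073
15-25,Magnocellular preoptic nucleus,0,0,0.082
15-25,Medial pretectal area,0,0,0.082
15-25,Substantia innominata,0,0,0.082
15-25,Accumbens shell,0,4,0.102
15-25,Medial septum,0,0,0.114
15-25,Lateral preoptic area,0,3,0.137
25-35,Ventral pallidum,0,5,0.022
25-35,Magnocellular preoptic nucleus,0,1,0.026
25-35,Secondary somatosensory ctx,4,32,0.056
25-35,Accumbens shell,0,6,0.069
25-35,Diagonal band of Broca,0,4,0.092
25-35,Caudal piriform ctx,0,23,0.097
25-35,Supramammillary nucleus,0,1,0.111
25-35,Inferior colliculus,62,85,0.121
35-45,Ventral pallidum,0,8,0.006
35-45,Accumbens shell,0,10,0.008
35-45,Diagonal band of Broca,0,7,0.008
35-45,Medial preoptic area,1,8,0.013
35-45,Infralimbic ctx,0,14,0.015
35-45,Substantia nigra reticularis,6,17,0.033
35-45,Periaqueductal gray thalamus,24,47,0.037
35-45,Magnocellular preoptic nucleus,0,1,0.042
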