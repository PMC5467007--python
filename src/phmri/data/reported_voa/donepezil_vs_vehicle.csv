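window,region_name,count_vehicle,count_treatment,p_value
15-25,Magnocellular preoptic nucleus,0,1,0.007
15-25,Dorsal raphe,0,8,0.012
15-25,Medial septum,0,3,0.02
15-25,Medial orbital ctx,0,16,0.022
15-25,Ventral pallidum,0,12,0.027
15-25,Medial geniculate,0,22,0.028
15-25,Insular ctx,14,107,0.03
15-25,Superior colliculus,29,112,0.03
15-25,Frontal association ctx,0,10,0.032
15-25,Inferior colliculus,41,108,0.034
15-25,Primary somatosensory ctx upper lip,0,41,0.041
15-25,Dentate gyrus ventral,1,39,0.043
15-25,Anterior olfactory nucleus,0,33,0.044
15-25,External plexiform layer,23,56,0.047
15-25,Dorsal paragigantocellularis nucleus,0,3,0.047
15-25,Ventral orbital ctx,0,4,0.048
15-25,Entorhinal ctx,27,147,0.048
15-25,Lateral geniculate,2,19,0.049
15-25,Intercalated amygdaloid nucleus,0,0,0.05
25-35,Accumbens shell,0,5,0.013
25-35,Infralimbic ctx,0,10,0.013
25-35,Medial septum,0,2,0.02
25-35,Magnocellular preoptic nucleus,0,2,0.021
25-35,Anterior olfactory nucleus,0,17,0.025
25-35,Lateral geniculate,3,12,0.046
25-35,Crus 2 of ansiform lobule,39,2,0.047
25-35,Ventral orbital ctx,0,4,0.06
25-35,Habenula nucleus,3,19,0.065
25-35,Dorsomedial tegmental area,0,2,0.072
25-35,Diagonal band of Broca,0,4,0.075
25-35,Medial geniculate,1,14,0.076
25-35,Subiculum dorsal,6,26,0.083
25-35,Entorhinal ctx,43,118,0.083
25-35,Dorsal raphe,0,3,0.084
25-35,Periaqueductal gray thalamus,9,55,0.092
25-35,Ventral pallidum,0,6,0.096
25-35,3rd cerebellar lobule,4,17,0.099
25-35,Frontal association ctx,0,6,0.103
35-45,Raphe obscurus nucleus,3,0,0.007
35-45,Infralimbic ctx,0,15,0.01
35-45,Ventral orbital ctx,0,7,0.016
35-45,Diagonal band of Broca,0,3,0.017
35-45,Crus 2 of ansiform lobule,39,4,0.021
35-45,8th cerebellar lobule,14,0,0.033
35-45,7th cerebellar lobule,15,0,0.04
35-45,Medial pretectal area,0,0,0.051
35-45,Accumbens shell,0,8,0.052
35-45,Gigantocellular reticular nucleus pons,33,11,0.054
35-45,6th cerebellar lobule,46,16,0.054
35-45,Crus 1 of ansiform lobule,52,14,0.054
35-45,Ventral pallidum,0,9,0.058
35-45,Dorsal raphe,0,3,0.059
35-45,Magnocellular preoptic nucleus,0,1,0.064
35-45,Paramedian lobule,38,12,0.065
35-45,Pontine nuclei,34,18,0.068
35-45,Neural lobe pituitary,6,3,0.07
35-45,Inferior olivary complex,13,3,0.076
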