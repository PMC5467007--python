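window,region_name,count_vehicle,count_treatment,p_value
15-25,Magnocellular preoptic nucleus,0,2,0.012
15-25,Medial preoptic area,0,25,0.014
15-25,Medial amygdaloid nucleus,2,12,0.014
15-25,Ventral pallidum,0,15,0.018
15-25,Median raphe nucleus,0,4,0.018
15-25,Anterior olfactory nucleus,0,32,0.019
15-25,Ventral tegmental area,0,4,0.03
15-25,Posterior hypothalamic area,0,12,0.03
15-25,Medial dorsal thalamic nucleus,0,9,0.031
15-25,Pedunculopontine tegmental area,0,4,0.033
15-25,Infralimbic ctx,0,19,0.033
15-25,Ventromedial thalamic nucleus,0,11,0.033
15-25,Granular cell layer,22,85,0.034
15-25,Accumbens shell,0,12,0.034
15-25,Triangular septal nucleus,1,5,0.034
15-25,Tenia tecta ctx,6,46,0.034
15-25,Cortical amygdaloid nucleus,11,26,0.037
15-25,Diagonal band of broca,0,4,0.038
15-25,Lateral preoptic area,0,7,0.039
15-25,3rd cerebellar lobule,2,7,0.04
15-25,Medial orbital ctx,0,15,0.042
15-25,Medial septum,0,1,0.044
15-25,Reuniens nucleus,0,2,0.044
15-25,Central medial thalamic nucleus,0,1,0.052
15-25,Raphe linear,0,1,0.052
15-25,Dorsal raphe,0,4,0.052
15-25,Lateral posterior thalamic nucleus,2,33,0.057
15-25,Primary somatosensory ctx trunk,0,10,0.058
15-25,Zona incerta,0,16,0.058
15-25,Primary somatosensory ctx upper lip,0,59,0.059
15-25,Dentate gyrus ventral,1,8,0.061
15-25,Anterior hypothalamic area,0,17,0.065
15-25,Intercalated amygdaloid nucleus,0,0,0.067
15-25,Medial pretectal area,0,0,0.067
15-25,Substantia nigra reticularis,0,24,0.072
15-25,Premammillary nucleus,2,4,0.073
25-35,Infralimbic ctx,0,39,0.006
25-35,Granular cell layer,15,81,0.006
25-35,Accumbens shell,0,13,0.006
25-35,Anterior olfactory nucleus,0,33,0.007
25-35,Lateral preoptic area,0,8,0.008
25-35,Habenula nucleus,3,18,0.009
25-35,Ventral pallidum,0,5,0.009
25-35,Triangular septal nucleus,0,9,0.012
25-35,Medial preoptic area,0,26,0.012
25-35,3rd cerebellar lobule,4,22,0.013
25-35,Lateral posterior thalamic nucleus,8,45,0.013
25-35,Periaqueductal gray thalamus,9,75,0.013
25-35,Accumbens core,0,2,0.013
25-35,Medial dorsal thalamic nucleus,2,11,0.019
25-35,Dentate gyrus ventral,4,24,0.019
25-35,Prelimbic ctx,1,18,0.023
25-35,Lateral septal nucleus,16,45,0.024
25-35,Bed nucleus stria terminalis,2,14,0.026
25-35,Diagonal band of Broca,0,7,0.026
25-35,Medial pretectal area,0,0,0.028
25-35,Tenia tecta ctx,8,47,0.029
25-35,Posterior hypothalamic area,0,18,0.03
25-35,Anterior cingulate area,4,50,0.03
25-35,Secondary somatosensory ctx,4,35,0.032
25-35,Frontal association ctx,0,7,0.032
25-35,Reuniens nucleus,0,3,0.033
25-35,Primary somatosensory ctx trunk,0,10,0.033
25-35,Magnocellular preoptic nucleus,0,1,0.035
25-35,Central gray,2,7,0.037
25-35,Parafascicular thalamic nucleus,2,21,0.037
25-35,External plexiform layer,29,43,0.038
25-35,Glomerular layer,23,92,0.038
25-35,Ventromedial thalamic nucleus,0,6,0.045
25-35,Premammillary nucleus,2,4,0.048
25-35,Dorsomedial tegmental area,0,5,0.05
25-35,Primary somatosensory ctx hindlimb,0,43,0.05
35-45,Infralimbic ctx,0,28,0.002
35-45,Medial orbital ctx,0,21,0.007
35-45,Triangular septal nucleus,3,10,0.011
35-45,Anterior olfactory nucleus,1,32,0.014
35-45,Accumbens shell,0,15,0.016
35-45,Entorhinal ctx,51,168,0.017
35-45,Ventral pallidum,0,4,0.018
35-45,Granular cell layer,36,75,0.019
35-45,Medial preoptic area,1,22,0.022
35-45,Tenia tecta ctx,6,42,0.023
35-45,Prelimbic ctx,5,12,0.026
35-45,Medial pretectal area,0,0,0.028
35-45,Lateral preoptic area,0,6,0.034
35-45,Anterior cingulate area,12,59,0.034
35-45,Lateral septal nucleus,16,40,0.034
35-45,Magnocellular preoptic nucleus,0,2,0.035
35-45,Accumbens core,0,2,0.039
35-45,Anterior hypothalamic area,2,10,0.049
35-45,Primary somatosensory ctx hindlimb,5,24,0.051
35-45,Anterior pretectal nucleus,9,19,0.051
35-45,Habenula nucleus,4,21,0.051
35-45,Lateral posterior thalamic nucleus,23,39,0.052
35-45,Ventral subiculum,19,50,0.052
35-45,Posterior hypothalamic area,2,15,0.053
35-45,3rd cerebellar lobule,7,15,0.057
35-45,Periaqueductal gray thalamus,24,48,0.058
35-45,Diagonal band of Broca,0,7,0.063
35-45,Extended amydala,0,2,0.063
35-45,Frontal association ctx,0,8,0.064
35-45,Medial dorsal thalamic nucleus,3,10,0.069
35-45,Medial amygdaloid nucleus,5,14,0.069
35-45,Dentate gyrus ventral,5,15,0.069
35-45,Ventrolateral thalamic nucleus,0,8,0.071
35-45,Cortical amygdaloid nucleus,11,24,0.077
35-45,Reuniens nucleus,0,3,0.081
35-45,Secondary motor ctx,39,53,0.084
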