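# Example stain-matrix config: one stain per line, "name r g b".
# Vectors are normalised to unit Euclidean norm on load.
# Haematoxylin and DAB are the published Ruifrok-Johnston values;
# Sirius Red is a unit vector estimated from synthetic pure-stain
# swatches (a red stain absorbs green and blue, transmits red).
haematoxylin 0.650 0.704 0.286
dab          0.268 0.570 0.776
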