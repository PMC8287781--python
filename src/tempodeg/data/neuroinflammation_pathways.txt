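# The 23 pathway annotations of the mouse neuroinflammation panel
# (public panel metadata; one name per line, editable fixture).
Adaptive Immune Response
Angiogenesis
Apoptosis
Astrocyte Function
Autophagy
Carbohydrate Metabolism
Cell Cycle
Cellular Stress
Cytokine Signaling
DNA Damage
Epigenetic Regulation
Growth Factor Signaling
Inflammatory Signaling
Innate Immune Response
Insulin Signaling
Lipid Metabolism
Matrix Remodeling
Microglia Function
Myeloid Cell Function
Neurons and Neurotransmission
NF-kB
Oligodendrocyte Function
Vascular Function
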