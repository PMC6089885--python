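>ZmPIP1;2_synthetic_standin plasma-membrane aquaporin PIP1 paralog; SYNTHETIC reconstruction, not the UniProt Q9XF59 entry
MEGKEEDVRLGANKFPERQPIGTSAQSTDKDYKEPPPAPLFEPGELSSWSFYRAGIAEFI
ATFLFLYITVLTVMGVKRSPNMCASVGIQGIAWSFGGMIFALAVYCTAGISGGHINPAVT
FGLFLARKLSLTRAVFYIVMQCLGAICGAGVVKGFQPGPYQTLGGGANTVAHGYTKGSGL
GAEIIGTFVLVYTVFSATDAKRNARDSHVPILAPLPIGFAVFLVHLATIPITGTGINPAR
SLGAAIIYNKSKPWDDHWIFWVGPFIGAALAAIYHQVIIRAIPFKSRS
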