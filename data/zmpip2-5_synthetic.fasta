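>ZmPIP2;5_synthetic_standin plasma-membrane aquaporin PIP2 paralog; SYNTHETIC reconstruction, not the UniProt Q9XF58 entry
MAKDIEVGDDGKDYKDPPPAPLFDAEELTKWSLYRAVIAEFIATLLFLYVTVATVIGYKH
QSDAAASGPDAACGGVGVLGIAWAFGGMIFVLIVYCTAGISGGHINPAVTFGLFLARKVS
LVRAVMYMVAQCLGAICGVGLVKAFQKAYYVRYGGGANELSAGYSKGTGLAAEIIGTFVL
VYTVFSATDPKRNARDSHVPVLAPLPIGFAVFMVHLATIPITGTGINPARSFGAAVIYNK
SKPWDDHWIFWVGPFIGAAIAALYHQYILRAGAIKALGSFRSNPTN
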