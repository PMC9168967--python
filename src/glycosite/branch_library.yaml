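# Default N-glycan antenna (branch) motif library: 12 motifs.
#
# Each motif is a linear residue chain ordered from the antenna root (the
# residue attached to the trimannosyl core) to the non-reducing terminus,
# plus optional terminal decorations (NeuAc capping, Fuc on the antenna).
# Linkage annotations (e.g. "b1-4") are recorded for documentation only and
# are never used in spectrum matching: HCD MS/MS cannot resolve them.
branches:
  - name: GlcNAc
    chain: [HexNAc]
    family: GlcNAc
    decorations: []
    linkage: "GlcNAcb1-2"
  - name: GlcNAc-F
    chain: [HexNAc]
    family: GlcNAc
    decorations: [Fuc]
    linkage: "Fuca1-3GlcNAc"
  - name: LacNAc
    chain: [HexNAc, Hex]
    family: LacNAc
    decorations: []
    linkage: "Galb1-4GlcNAc"
  - name: LacNAc-S
    chain: [HexNAc, Hex]
    family: LacNAc
    decorations: [NeuAc]
    linkage: "NeuAca2-6Galb1-4GlcNAc"
  - name: LacNAc-F
    chain: [HexNAc, Hex]
    family: LacNAc
    decorations: [Fuc]
    linkage: "Galb1-4(Fuca1-3)GlcNAc"
  - name: LacNAc-FS
    chain: [HexNAc, Hex]
    family: LacNAc
    decorations: [Fuc, NeuAc]
    linkage: "NeuAca2-6Galb1-4(Fuca1-3)GlcNAc"
  - name: LacdiNAc
    chain: [HexNAc, HexNAc]
    family: LacdiNAc
    decorations: []
    linkage: "GalNAcb1-4GlcNAc"
  - name: LacdiNAc-S
    chain: [HexNAc, HexNAc]
    family: LacdiNAc
    decorations: [NeuAc]
    linkage: "NeuAca2-6GalNAcb1-4GlcNAc"
  - name: LacdiNAc-F
    chain: [HexNAc, HexNAc]
    family: LacdiNAc
    decorations: [Fuc]
    linkage: "GalNAcb1-4(Fuca1-3)GlcNAc"
  - name: Man
    chain: [Hex]
    family: Mannose
    decorations: []
    linkage: "Mana1-2"
  - name: Man2
    chain: [Hex, Hex]
    family: Mannose
    decorations: []
    linkage: "Mana1-2Mana1-2"
  - name: TGal
    # terminal galactose directly on a core mannose; Hex-initiated like the
    # mannose motifs and therefore spectrally indistinguishable from Man
    chain: [Hex]
    family: Mannose
    decorations: []
    linkage: "Galb1-4"
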