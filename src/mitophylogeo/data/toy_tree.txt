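# Toy haplogroup tree bundled for tests, demos and the synthetic study.
# A deliberately small phylogeny loosely modelled on the human mtDNA tree;
# nested clade definitions follow published motifs where available, the
# remaining branches are synthetic. Not a substitute for PhyloTree.
root:
  HV: T14766C
    H: G2706A
      H92: T9497C,T16368C
      H97: A111G,T195C,T16209C,C16261T
    HV9: T16311C
      HV9c: T6248C,@16311
        HV9c1: G5471A
  JT: G11719A
    J: C295T,C16069T
      J1d: C462T,T489C,T16126C,C16193T
        J1d6: A10283G
      J1b1a3a: G8269A,T16145C
    T: T16126C,C16294T
      T2: A11812G
        T2d2: G16153A
          T2d2a: T6253C
        T2n: C150T
          T2n1: A6722G
  U: A11467G
    U7: A980G,T5111C
      U7a: A14569G
        U7a4: T146C,T16126C
          U7a4a: C16148T
            U7a4a1: T195C,T6221C
              U7a4a1a: A16318C
                U7a4a1a1: C8574T
                  U7a4a1a1a: G16213A
              U7a4a1b: T143C,C12063T,A15322G
  L1b1a: G3666A
    L1b1a5: C14812T
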