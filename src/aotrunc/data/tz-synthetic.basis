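# SYNTHETIC triple-zeta-like basis for structural tests only.
# Composition mirrors an augmented triple-zeta set (H: 3s3p1d, O: 6s4p3d1f)
# but the exponents are synthetic even-tempered-style values, not a
# published basis. Do not use for quantitative electronic structure.
BASIS
H    S
      4.5000000      1.0000000
H    S
      0.7000000      1.0000000
H    S
      0.1600000      1.0000000
H    P
      1.4000000      1.0000000
H    P
      0.4500000      1.0000000
H    P
      0.1200000      1.0000000
H    D
      1.0000000      1.0000000
O    S
   2266.0000000      1.0000000
O    S
    340.0000000      1.0000000
O    S
     77.0000000      1.0000000
O    S
     21.5000000      1.0000000
O    S
      6.6000000      1.0000000
O    S
      0.8100000      1.0000000
O    P
     17.7000000      1.0000000
O    P
      3.8600000      1.0000000
O    P
      1.0500000      1.0000000
O    P
      0.2800000      1.0000000
O    D
      3.0000000      1.0000000
O    D
      1.0000000      1.0000000
O    D
      0.3000000      1.0000000
O    F
      1.4000000      1.0000000
END
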