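# 6-31++G**: 6-31G plus diffuse s (H, alpha 0.036) / sp (O, alpha 0.0845)
# and polarization p (H, alpha 1.1) / d (O, alpha 0.8); standard values.
BASIS
H    S
     18.7311370      0.03349460
      2.8253937      0.23472695
      0.6401217      0.81375733
H    S
      0.1612778      1.0000000
H    S
      0.0360000      1.0000000
H    P
      1.1000000      1.0000000
O    S
   5484.6716600      0.0018311
    825.2349460      0.0139501
    188.0469580      0.0684451
     52.9645000      0.2327143
     16.8975704      0.4701930
      5.7996353      0.3585209
O    SP
     15.5396162     -0.1107775      0.0708743
      3.5999336     -0.1480263      0.3397528
      1.0137618      1.1307670      0.7271586
O    SP
      0.2700058      1.0000000      1.0000000
O    SP
      0.0845000      1.0000000      1.0000000
O    D
      0.8000000      1.0000000
END
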