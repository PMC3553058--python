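! H2/O2 combustion mechanism (O Conaire et al., Int. J. Chem. Kinet. 36, 2004)
! 19 reversible reactions; Arrhenius parameters retained for reference only.
ELEMENTS
H O N AR
END
SPECIES
H2 O2 O H OH H2O N2 HO2 H2O2 AR
END
REACTIONS
H+O2=O+OH                 1.915E+14  0.00  1.644E+04
O+H2=H+OH                 5.080E+04  2.67  6.292E+03
OH+H2=H+H2O               2.160E+08  1.51  3.430E+03
O+H2O=OH+OH               2.970E+06  2.02  1.340E+04
H2+M=H+H+M                4.577E+19 -1.40  1.044E+05
O+O+M=O2+M                6.165E+15 -0.50  0.000E+00
O+H+M=OH+M                4.714E+18 -1.00  0.000E+00
H+OH+M=H2O+M              2.212E+22 -2.00  0.000E+00
H+O2(+M)=HO2(+M)          1.475E+12  0.60  0.000E+00
HO2+H=H2+O2               1.660E+13  0.00  8.230E+02
HO2+H=OH+OH               7.079E+13  0.00  2.950E+02
HO2+O=OH+O2               3.250E+13  0.00  0.000E+00
HO2+OH=H2O+O2             2.890E+13  0.00 -4.970E+02
H2O2+O2=HO2+HO2           4.634E+16 -0.35  5.067E+04
H2O2(+M)=OH+OH(+M)        2.951E+14  0.00  4.843E+04
H2O2+H=H2O+OH             2.410E+13  0.00  3.970E+03
H2O2+H=H2+HO2             6.025E+13  0.00  7.950E+03
H2O2+O=OH+HO2             9.550E+06  2.00  3.970E+03
H2O2+OH=H2O+HO2           1.000E+12  0.00  0.000E+00
END
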