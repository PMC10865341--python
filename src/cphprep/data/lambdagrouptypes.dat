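# Default titratable group types shipped with cphprep.
#
# ASPT and HSPT carry published reference values (CHARMM36m-based
# constant-pH parameter set; HSPT dvdl lines keep the published leading
# coefficients).  GLUT is a SYNTHETIC placeholder: its reference pKa (4.25)
# is the standard glutamate value, but its charges mirror the aspartate
# carboxyl entry and are meant for testing the setup pipeline, not for
# production force-field work.  BUF is the standard +-0.5 charge buffer
# particle (zero charge at lambda = 0.5).

ffname = charmm36m-cph
water = tip3p
gmxpath = /usr/local/gromacs-cph

[ ASPT ]
incl = ASP ASP1 ASPH ASPP ASH
atoms = CB CG OD1 OD2 HD2
qqA = -0.21 0.75 -0.55 -0.61 0.44
pKa_1 = 3.65
qqB_1 = -0.28 0.62 -0.76 -0.76 0.00
dvdl_1 = -54.078 -144.280 278.550 -146.030 -554.270 44.621

[ GLUT ]
incl = GLU GLU1 GLUH GLUP GLH
atoms = CB CG CD OE1 OE2 HE2
qqA = 0.00 -0.21 0.75 -0.55 -0.61 0.44
pKa_1 = 4.25
qqB_1 = 0.00 -0.28 0.62 -0.76 -0.76 0.00
dvdl_1 = -54.078 -144.280 278.550 -146.030 -554.270 44.621

[ HSPT ]
incl = HIS HIS1 HISA HISB HISH HISD HISE HISP HSD HSE HSP
atoms = CB CD2 HD2 CG NE2 HE2 ND1 HD1 CE1 HE1
qqA = 0.00 0.00 0.00 0.00 0.00 0.00 0.00 0.00 0.00 0.00
pKa_1 = 0.0
qqB_1 = -0.05 0.19 0.13 0.19 -0.51 0.44 -0.51 0.44 0.32 0.18
dvdl_1 = -3015.4 -13444.1 -34779.0
pKa_2 = 6.53
qqB_2 = -0.08 -0.05 0.09 0.22 -0.36 0.32 -0.7 0.0 0.25 0.13
dvdl_2 = -1695.49 -8107.68 -22614.3
pKa_3 = 6.92
qqB_3 = -0.09 0.22 0.1 -0.05 -0.7 0.0 -0.36 0.32 0.25 0.13
dvdl_3 = -111.044 -768.566 -9092.12

[ BUF ]
incl = BUF
atoms = BUF
qqA = 0.5
pKa_1 = 0.0
qqB_1 = -0.5
dvdl_1 = 0.0 0.0 0.0 0.0 0.0 0.0
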