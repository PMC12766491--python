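# Whewellite (calcium oxalate monohydrate, CaC2O4.H2O) structural model
# Model coordinates (synthetic reconstruction; see
# scripts/build_mineral_models.py): published unit cell and
# space-group packing, rigid idealized molecular fragments, packing
# fitted to the mineral's published powder-diffraction line
# intensities. Not refined experimental atomic coordinates.
# Underlying space group of the model: P2_1/n, b unique, Z=8 (b/2 pseudo-translation built in); expressed in P1.
data_COM
_cell_length_a 9.9763
_cell_length_b 14.5884
_cell_length_c 6.2907
_cell_angle_alpha 90.00
_cell_angle_beta 107.05
_cell_angle_gamma 90.00
_symmetry_space_group_name_H-M 'P 1'
loop_
_symmetry_equiv_pos_as_xyz
'x, y, z'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
_atom_site_occupancy
Ca1 Ca 0.41022 0.25613 0.73403 1.000
Ca2 Ca 0.40221 0.74399 0.72971 1.000
Ca3 Ca 0.09734 0.50160 0.77780 1.000
Ca4 Ca 0.09690 0.00212 0.76763 1.000
Ca5 Ca 0.58947 0.25638 0.27075 1.000
Ca6 Ca 0.59714 0.74493 0.26881 1.000
Ca7 Ca 0.90094 0.99734 0.23306 1.000
Ca8 Ca 0.90018 0.49830 0.23010 1.000
C1 C 0.90560 0.24036 0.23164 1.000
C2 C 0.90995 0.73965 0.23362 1.000
C3 C 0.59195 0.49307 0.26837 1.000
C4 C 0.59836 0.98872 0.27227 1.000
C5 C 0.09012 0.25480 0.77232 1.000
C6 C 0.08997 0.75708 0.76192 1.000
C7 C 0.39988 0.01116 0.72787 1.000
C8 C 0.41139 0.51602 0.73207 1.000
C9 C 0.90685 0.21388 0.47561 1.000
C10 C 0.91031 0.71237 0.47790 1.000
C11 C 0.59371 0.46514 0.02397 1.000
C12 C 0.58843 0.96471 0.02659 1.000
C13 C 0.08621 0.28464 0.52491 1.000
C14 C 0.08596 0.78590 0.53202 1.000
C15 C 0.40815 0.04125 0.97423 1.000
C16 C 0.41191 0.53439 0.97073 1.000
O1 O 0.02436 0.22690 0.17828 1.000
O2 O 0.01912 0.73073 0.17517 1.000
O3 O 0.48109 0.47627 0.32283 1.000
O4 O 0.48670 0.97727 0.32483 1.000
O5 O 0.98412 0.27841 0.82171 1.000
O6 O 0.98162 0.77703 0.82345 1.000
O7 O 0.51791 0.02058 0.67622 1.000
O8 O 0.51819 0.51818 0.67334 1.000
O9 O 0.79953 0.28638 0.11615 1.000
O10 O 0.79761 0.77401 0.11587 1.000
O11 O 0.69215 0.02719 0.38438 1.000
O12 O 0.70008 0.53667 0.37581 1.000
O13 O 0.20207 0.22289 0.88757 1.000
O14 O 0.19575 0.72074 0.87972 1.000
O15 O 0.29733 0.47339 0.61496 1.000
O16 O 0.29705 0.97335 0.61501 1.000
O17 O 0.80478 0.22727 0.52183 1.000
O18 O 0.79991 0.72855 0.52532 1.000
O19 O 0.69364 0.47762 0.97085 1.000
O20 O 0.70041 0.97921 0.96929 1.000
O21 O 0.19729 0.26140 0.46785 1.000
O22 O 0.19625 0.76329 0.46975 1.000
O23 O 0.30417 0.02698 0.03058 1.000
O24 O 0.31070 0.52895 0.02243 1.000
O25 O 0.02088 0.17566 0.59116 1.000
O26 O 0.01950 0.67872 0.59377 1.000
O27 O 0.47212 0.43006 0.90662 1.000
O28 O 0.48244 0.92854 0.90869 1.000
O29 O 0.98617 0.32728 0.40934 1.000
O30 O 0.97921 0.83338 0.41488 1.000
O31 O 0.52559 0.07458 0.09304 1.000
O32 O 0.52238 0.56761 0.09433 1.000
O33 O 0.78475 0.39283 0.51471 1.000
O34 O 0.78210 0.89953 0.52420 1.000
O35 O 0.71698 0.14046 0.98532 1.000
O36 O 0.71624 0.64126 0.97359 1.000
O37 O 0.21265 0.10328 0.47968 1.000
O38 O 0.21931 0.60065 0.48345 1.000
O39 O 0.28590 0.35409 0.01307 1.000
O40 O 0.29080 0.84386 0.01653 1.000
H1 H 0.85518 0.44343 0.51204 1.000
H2 H 0.85513 0.93412 0.51177 1.000
H3 H 0.63844 0.18939 0.97884 1.000
H4 H 0.63396 0.68755 0.98253 1.000
H5 H 0.14352 0.05803 0.48191 1.000
H6 H 0.14430 0.55730 0.48227 1.000
H7 H 0.35777 0.30551 0.01676 1.000
H8 H 0.36371 0.82025 0.01146 1.000
H9 H 0.71059 0.44308 0.52211 1.000
H10 H 0.70513 0.93990 0.51481 1.000
H11 H 0.79530 0.19343 0.98169 1.000
H12 H 0.79394 0.69208 0.98555 1.000
H13 H 0.29041 0.06678 0.48462 1.000
H14 H 0.29368 0.56146 0.48548 1.000
H15 H 0.21100 0.30623 0.01379 1.000
H16 H 0.19999 0.81309 0.01881 1.000
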