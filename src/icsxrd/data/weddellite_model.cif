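# Weddellite (calcium oxalate dihydrate, CaC2O4.2H2O) structural model
# Model coordinates (synthetic reconstruction; see
# scripts/build_mineral_models.py): published unit cell and
# space-group packing, rigid idealized molecular fragments, packing
# fitted to the mineral's published powder-diffraction line
# intensities. Not refined experimental atomic coordinates.
# Underlying space group of the model: I4/m, Z=8; expressed in P1.
data_COD
_cell_length_a 12.3710
_cell_length_b 12.3710
_cell_length_c 7.3570
_cell_angle_alpha 90.00
_cell_angle_beta 90.00
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
Ca1 Ca 0.26131 0.47721 0.00000 1.000
Ca2 Ca 0.73869 0.52279 0.00000 1.000
Ca3 Ca 0.52279 0.26131 0.00000 1.000
Ca4 Ca 0.47721 0.73869 0.00000 1.000
Ca5 Ca 0.76131 0.97721 0.50000 1.000
Ca6 Ca 0.23869 0.02279 0.50000 1.000
Ca7 Ca 0.02279 0.76131 0.50000 1.000
Ca8 Ca 0.97721 0.23869 0.50000 1.000
C1 C 0.26560 0.16292 0.00000 1.000
C2 C 0.73440 0.83708 0.00000 1.000
C3 C 0.83708 0.26560 0.00000 1.000
C4 C 0.16292 0.73440 0.00000 1.000
C5 C 0.76560 0.66292 0.50000 1.000
C6 C 0.23440 0.33708 0.50000 1.000
C7 C 0.33708 0.76560 0.50000 1.000
C8 C 0.66292 0.23440 0.50000 1.000
C9 C 0.26489 0.03682 0.00000 1.000
C10 C 0.73511 0.96318 0.00000 1.000
C11 C 0.96318 0.26489 0.00000 1.000
C12 C 0.03682 0.73511 0.00000 1.000
C13 C 0.76489 0.53682 0.50000 1.000
C14 C 0.23511 0.46318 0.50000 1.000
C15 C 0.46318 0.76489 0.50000 1.000
C16 C 0.53682 0.23511 0.50000 1.000
O1 O 0.17583 0.20929 0.00000 1.000
O2 O 0.82417 0.79071 0.00000 1.000
O3 O 0.79071 0.17583 0.00000 1.000
O4 O 0.20929 0.82417 0.00000 1.000
O5 O 0.67583 0.70929 0.50000 1.000
O6 O 0.32417 0.29071 0.50000 1.000
O7 O 0.29071 0.67583 0.50000 1.000
O8 O 0.70929 0.32417 0.50000 1.000
O9 O 0.35588 0.20829 0.00000 1.000
O10 O 0.64412 0.79171 0.00000 1.000
O11 O 0.79171 0.35588 0.00000 1.000
O12 O 0.20829 0.64412 0.00000 1.000
O13 O 0.85588 0.70829 0.50000 1.000
O14 O 0.14412 0.29171 0.50000 1.000
O15 O 0.29171 0.85588 0.50000 1.000
O16 O 0.70829 0.14412 0.50000 1.000
O17 O 0.35467 0.99045 0.00000 1.000
O18 O 0.64533 0.00955 0.00000 1.000
O19 O 0.00955 0.35467 0.00000 1.000
O20 O 0.99045 0.64533 0.00000 1.000
O21 O 0.85467 0.49045 0.50000 1.000
O22 O 0.14533 0.50955 0.50000 1.000
O23 O 0.50955 0.85467 0.50000 1.000
O24 O 0.49045 0.14533 0.50000 1.000
O25 O 0.17461 0.99145 0.00000 1.000
O26 O 0.82539 0.00855 0.00000 1.000
O27 O 0.00855 0.17461 0.00000 1.000
O28 O 0.99145 0.82539 0.00000 1.000
O29 O 0.67461 0.49145 0.50000 1.000
O30 O 0.32539 0.50855 0.50000 1.000
O31 O 0.50855 0.67461 0.50000 1.000
O32 O 0.49145 0.32539 0.50000 1.000
O33 O 0.24922 0.15816 0.24473 1.000
O34 O 0.24922 0.15816 0.75527 1.000
O35 O 0.75078 0.84184 0.24473 1.000
O36 O 0.75078 0.84184 0.75527 1.000
O37 O 0.84184 0.24922 0.24473 1.000
O38 O 0.84184 0.24922 0.75527 1.000
O39 O 0.15816 0.75078 0.24473 1.000
O40 O 0.15816 0.75078 0.75527 1.000
O41 O 0.74922 0.65816 0.74473 1.000
O42 O 0.74922 0.65816 0.25527 1.000
O43 O 0.25078 0.34184 0.74473 1.000
O44 O 0.25078 0.34184 0.25527 1.000
O45 O 0.34184 0.74922 0.74473 1.000
O46 O 0.34184 0.74922 0.25527 1.000
O47 O 0.65816 0.25078 0.74473 1.000
O48 O 0.65816 0.25078 0.25527 1.000
H1 H 0.31066 0.20585 0.24473 1.000
H2 H 0.31066 0.20585 0.75527 1.000
H3 H 0.68934 0.79415 0.24473 1.000
H4 H 0.68934 0.79415 0.75527 1.000
H5 H 0.79415 0.31066 0.24473 1.000
H6 H 0.79415 0.31066 0.75527 1.000
H7 H 0.20585 0.68934 0.24473 1.000
H8 H 0.20585 0.68934 0.75527 1.000
H9 H 0.81066 0.70585 0.74473 1.000
H10 H 0.81066 0.70585 0.25527 1.000
H11 H 0.18934 0.29415 0.74473 1.000
H12 H 0.18934 0.29415 0.25527 1.000
H13 H 0.29415 0.81066 0.74473 1.000
H14 H 0.29415 0.81066 0.25527 1.000
H15 H 0.70585 0.18934 0.74473 1.000
H16 H 0.70585 0.18934 0.25527 1.000
H17 H 0.18779 0.20585 0.24473 1.000
H18 H 0.18779 0.20585 0.75527 1.000
H19 H 0.81221 0.79415 0.24473 1.000
H20 H 0.81221 0.79415 0.75527 1.000
H21 H 0.79415 0.18779 0.24473 1.000
H22 H 0.79415 0.18779 0.75527 1.000
H23 H 0.20585 0.81221 0.24473 1.000
H24 H 0.20585 0.81221 0.75527 1.000
H25 H 0.68779 0.70585 0.74473 1.000
H26 H 0.68779 0.70585 0.25527 1.000
H27 H 0.31221 0.29415 0.74473 1.000
H28 H 0.31221 0.29415 0.25527 1.000
H29 H 0.29415 0.68779 0.74473 1.000
H30 H 0.29415 0.68779 0.25527 1.000
H31 H 0.70585 0.31221 0.74473 1.000
H32 H 0.70585 0.31221 0.25527 1.000
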