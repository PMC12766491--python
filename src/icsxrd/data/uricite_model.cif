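# Uricite (anhydrous uric acid, C5H4N4O3) structural model
# Model coordinates (synthetic reconstruction; see
# scripts/build_mineral_models.py): published unit cell and
# space-group packing, rigid idealized molecular fragments, packing
# fitted to the mineral's published powder-diffraction line
# intensities. Not refined experimental atomic coordinates.
# Underlying space group of the model: P2_1/a, b unique, Z=4; expressed in P1.
data_UA
_cell_length_a 14.4640
_cell_length_b 7.4030
_cell_length_c 6.2080
_cell_angle_alpha 90.00
_cell_angle_beta 65.10
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
C1 C 0.11316 0.61349 0.57339 1.000
C2 C 0.38684 0.11349 0.42661 1.000
C3 C 0.88684 0.38651 0.42661 1.000
C4 C 0.61316 0.88651 0.57339 1.000
N1 N 0.13638 0.56450 0.34011 1.000
N2 N 0.36362 0.06450 0.65989 1.000
N3 N 0.86362 0.43550 0.65989 1.000
N4 N 0.63638 0.93550 0.34011 1.000
C5 C 0.12551 0.38595 0.28543 1.000
C6 C 0.37449 0.88595 0.71457 1.000
C7 C 0.87449 0.61405 0.71457 1.000
C8 C 0.62551 0.11405 0.28543 1.000
C9 C 0.09141 0.25639 0.46404 1.000
C10 C 0.40859 0.75639 0.53596 1.000
C11 C 0.90859 0.74361 0.53596 1.000
C12 C 0.59141 0.24361 0.46404 1.000
C13 C 0.06819 0.30538 0.69732 1.000
C14 C 0.43181 0.80538 0.30268 1.000
C15 C 0.93181 0.69462 0.30268 1.000
C16 C 0.56819 0.19462 0.69732 1.000
N5 N 0.07906 0.48393 0.75200 1.000
N6 N 0.42094 0.98393 0.24800 1.000
N7 N 0.92094 0.51607 0.24800 1.000
N8 N 0.57906 0.01607 0.75200 1.000
N9 N 0.14282 0.30104 0.07212 1.000
N10 N 0.35718 0.80104 0.92788 1.000
N11 N 0.85718 0.69896 0.92788 1.000
N12 N 0.64282 0.19896 0.07212 1.000
C17 C 0.11943 0.11900 0.11890 1.000
C18 C 0.38057 0.61900 0.88110 1.000
C19 C 0.88057 0.88100 0.88110 1.000
C20 C 0.61943 0.38100 0.11890 1.000
N13 N 0.08765 0.09141 0.36112 1.000
N14 N 0.41235 0.59141 0.63888 1.000
N15 N 0.91235 0.90859 0.63888 1.000
N16 N 0.58765 0.40859 0.36112 1.000
O1 O 0.12278 0.77149 0.62177 1.000
O2 O 0.37722 0.27149 0.37823 1.000
O3 O 0.87722 0.22851 0.37823 1.000
O4 O 0.62278 0.72851 0.62177 1.000
O5 O 0.03802 0.19074 0.85537 1.000
O6 O 0.46198 0.69074 0.14463 1.000
O7 O 0.96198 0.80926 0.14463 1.000
O8 O 0.53802 0.30926 0.85537 1.000
O9 O 0.12574 0.00275 0.97179 1.000
O10 O 0.37426 0.50275 0.02821 1.000
O11 O 0.87426 0.99725 0.02821 1.000
O12 O 0.62574 0.49725 0.97179 1.000
H1 H 0.06219 0.51953 0.92151 1.000
H2 H 0.43781 0.01953 0.07849 1.000
H3 H 0.93781 0.48047 0.07849 1.000
H4 H 0.56219 0.98047 0.92151 1.000
H5 H 0.16116 0.65864 0.21033 1.000
H6 H 0.33884 0.15864 0.78967 1.000
H7 H 0.83884 0.34136 0.78967 1.000
H8 H 0.66116 0.84136 0.21033 1.000
H9 H 0.06569 0.97238 0.44722 1.000
H10 H 0.43431 0.47238 0.55278 1.000
H11 H 0.93431 0.02762 0.55278 1.000
H12 H 0.56569 0.52762 0.44722 1.000
H13 H 0.16799 0.36107 0.91137 1.000
H14 H 0.33201 0.86107 0.08863 1.000
H15 H 0.83201 0.63893 0.08863 1.000
H16 H 0.66799 0.13893 0.91137 1.000
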