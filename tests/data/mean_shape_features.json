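{
"note": "frozen feature vector of the symmetric mean shape (regression oracle)",
"names": [
"dist_eye_width_l",
"dist_eye_width_r",
"dist_eye_opening_outer_l",
"dist_eye_opening_inner_l",
"dist_eye_opening_outer_r",
"dist_eye_opening_inner_r",
"dist_intercanthal",
"dist_outercanthal",
"dist_brow_length_l",
"dist_brow_length_r",
"dist_brow_eye_gap_l",
"dist_brow_eye_gap_r",
"dist_interbrow",
"dist_glabella_nasion",
"dist_nasal_dorsum",
"dist_nose_length",
"dist_nose_width",
"dist_alar_base_width",
"dist_tip_subnasale",
"dist_philtrum_length",
"dist_mouth_width",
"dist_upper_lip_height",
"dist_lower_lip_height",
"dist_lip_height",
"dist_lip_menton",
"dist_stomion_menton",
"dist_upper_third",
"dist_middle_third",
"dist_lower_third",
"dist_face_height",
"dist_bizygomatic_width",
"dist_malar_width",
"dist_arch_width",
"dist_bigonial_width",
"dist_temple_width",
"dist_chin_width",
"dist_menton_pogonion",
"dist_subnasale_stomion",
"dist_endocanthion_tip_l",
"dist_endocanthion_tip_r",
"dist_eye_mouth_l",
"dist_eye_mouth_r",
"dist_browpeak_separation",
"dist_orbital_height_l",
"dist_orbital_height_r",
"dist_zygion_menton_l",
"dist_zygion_menton_r",
"dist_nasion_menton",
"dist_trichion_subnasale",
"dist_cheilion_menton_l",
"dist_cheilion_menton_r",
"dist_glabella_menton",
"ratio_eye_width_l_over_intercanthal",
"ratio_eye_width_r_over_intercanthal",
"ratio_eye_width_l_over_outercanthal",
"ratio_eye_width_r_over_outercanthal",
"ratio_intercanthal_over_outercanthal",
"ratio_eye_opening_outer_l_over_eye_width_l",
"ratio_eye_opening_outer_r_over_eye_width_r",
"ratio_eye_opening_inner_l_over_eye_width_l",
"ratio_eye_opening_inner_r_over_eye_width_r",
"ratio_brow_length_l_over_brow_length_r",
"ratio_eye_width_l_over_eye_width_r",
"ratio_nose_width_over_bizygomatic_width",
"ratio_mouth_width_over_bizygomatic_width",
"ratio_nose_width_over_mouth_width",
"ratio_upper_lip_height_over_lower_lip_height",
"ratio_philtrum_length_over_lower_third",
"ratio_upper_third_over_middle_third",
"ratio_middle_third_over_lower_third",
"ratio_upper_third_over_lower_third",
"ratio_bizygomatic_width_over_face_height",
"ratio_bigonial_width_over_bizygomatic_width",
"ratio_chin_width_over_bigonial_width",
"ratio_temple_width_over_bizygomatic_width",
"ratio_malar_width_over_bizygomatic_width",
"ratio_interbrow_over_intercanthal",
"ratio_nose_length_over_face_height",
"ratio_lip_height_over_lower_third",
"ratio_lip_menton_over_lower_third",
"ratio_tip_subnasale_over_nose_length",
"ratio_alar_base_width_over_nose_width",
"ratio_glabella_nasion_over_nose_length",
"ratio_brow_eye_gap_l_over_brow_eye_gap_r",
"ratio_orbital_height_l_over_orbital_height_r",
"ratio_endocanthion_tip_l_over_endocanthion_tip_r",
"ratio_eye_mouth_l_over_eye_mouth_r",
"ratio_zygion_menton_l_over_zygion_menton_r",
"ratio_cheilion_menton_l_over_cheilion_menton_r",
"ratio_subnasale_stomion_over_lower_third",
"angle_nasofrontal_pt",
"angle_nasal_tip",
"angle_alar_base_spread",
"angle_alare_spread",
"angle_jaw_l",
"angle_jaw_r",
"angle_brow_arch_l",
"angle_brow_arch_r",
"angle_canthal_outer_l",
"angle_canthal_outer_r",
"angle_canthal_inner_l",
"angle_canthal_inner_r",
"angle_mouth_corner_l",
"angle_mouth_corner_r",
"angle_chin_apex",
"angle_cupid_bow",
"angle_lower_lip_arc",
"angle_zygion_nasion_spread",
"angle_exocanthion_glabella",
"angle_gonial_spread",
"angle_endocanthion_nasion",
"angle_browpeak_glabella",
"angle_cheilion_tip_spread",
"angle_zygion_menton_spread",
"angle_browouter_trichion",
"ma_width_height_ratio",
"ma_thirds_proportion",
"ma_five_eye_ratio",
"ma_fissure_aspect",
"ma_intercanthal_ratio",
"ma_ptosis_index",
"ma_alar_width_ratio",
"ma_nasofrontal_angle",
"ma_nasal_bridge_deviation",
"ma_lip_width_ratio",
"ma_philtrum_length_ratio",
"ma_lip_thickness_ratio",
"ma_jaw_angle",
"ma_chin_width_ratio",
"ma_zygomatic_symmetry",
"ma_brow_peak_symmetry",
"ma_mouth_corner_offset",
"ma_zygomatic_chin_ratio",
"ma_eye_nose_ratio",
"ma_frontotemporal_ratio"
],
"values": [
0.329545454545,
0.329545454545,
0.090909090909,
0.090909090909,
0.090909090909,
0.090909090909,
0.340909090909,
1.0,
0.431967677472,
0.431967677472,
0.240791137505,
0.240791137505,
0.272727272727,
0.136363636364,
0.477272727273,
0.613636363636,
0.431818181818,
0.363636363636,
0.136363636364,
0.238636363636,
0.545454545455,
0.079545454545,
0.113636363636,
0.193181818182,
0.363636363636,
0.477272727273,
0.727272727273,
0.75,
0.795454545455,
2.272727272727,
1.636363636364,
1.181818181818,
1.454545454545,
1.318181818182,
1.590909090909,
0.5,
0.113636363636,
0.318181818182,
0.360963185779,
0.360963185779,
0.794561186655,
0.794561186655,
0.681818181818,
0.295454545455,
0.295454545455,
1.363636363636,
1.363636363636,
1.409090909091,
1.477272727273,
0.559594193284,
0.559594193284,
1.545454545455,
0.966666666667,
0.966666666667,
0.329545454545,
0.329545454545,
0.340909090909,
0.275862068966,
0.275862068966,
0.275862068966,
0.275862068966,
1.0,
1.0,
0.263888888889,
0.333333333333,
0.791666666667,
0.7,
0.3,
0.969696969697,
0.942857142857,
0.914285714286,
0.72,
0.805555555556,
0.379310344828,
0.972222222222,
0.722222222222,
0.8,
0.27,
0.242857142857,
0.457142857143,
0.222222222222,
0.842105263158,
0.222222222222,
1.0,
1.0,
1.0,
1.0,
1.0,
1.0,
0.4,
180.0,
180.0,
138.887909560833,
115.448711370845,
132.211113028801,
132.211113028801,
147.776644769252,
147.776644769252,
59.489762593884,
59.489762593884,
36.869897645844,
36.869897645844,
38.65980825409,
38.65980825409,
149.489762593884,
151.927513064147,
130.752870427673,
137.498988985734,
118.841546255022,
122.226836466179,
93.949868021764,
172.371850331419,
63.215004492498,
73.739795291688,
69.555662732728,
0.72,
1.09375,
1.006944444444,
3.625,
1.041666666667,
0.172413793103,
1.0,
180.0,
0.0,
1.263157894737,
0.3,
0.7,
132.211113028801,
0.379310344828,
0.0,
0.0,
0.0,
3.272727272727,
0.763157894737,
0.972222222222
]
}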