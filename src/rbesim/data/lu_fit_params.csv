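geometry,internalization,arrangement,b_init,b_init_sd,b_repair,b_repair_sd,a_repair,a_repair_sd
1,internalized,planar_2d,76.75,0.82,16.84,1.57,0.30,0.91
1,membrane_bound,planar_2d,77.17,0.86,17.00,1.68,0.00,1.23
2,internalized,planar_2d,79.13,1.02,15.91,1.91,1.36,1.33
2,membrane_bound,planar_2d,78.00,1.13,15.42,2.08,1.06,1.88
3,internalized,planar_2d,79.31,1.23,17.13,2.53,0.00,2.58
3,membrane_bound,planar_2d,77.18,1.35,11.63,2.35,4.51,2.95
4,internalized,planar_2d,78.28,1.13,14.84,2.01,2.67,2.15
4,membrane_bound,planar_2d,76.40,1.13,9.43,2.08,6.89,2.01
5,internalized,planar_2d,78.78,1.11,16.54,2.17,0.43,2.26
5,membrane_bound,planar_2d,75.57,1.03,14.27,2.26,1.87,2.82
1,internalized,lattice_3d,77.69,0.43,16.31,0.81,1.21,0.12
1,membrane_bound,lattice_3d,78.28,0.44,15.50,0.99,1.45,0.16
2,internalized,lattice_3d,76.89,0.47,15.05,1.10,1.32,0.16
2,membrane_bound,lattice_3d,78.93,0.39,14.87,0.88,1.49,0.14
3,internalized,lattice_3d,76.94,0.44,14.41,0.96,1.49,0.14
3,membrane_bound,lattice_3d,76.59,0.43,16.35,0.94,1.11,0.14
4,internalized,lattice_3d,77.19,0.43,14.48,1.09,1.48,0.16
4,membrane_bound,lattice_3d,77.57,0.37,15.73,0.85,1.30,0.12
5,internalized,lattice_3d,77.41,0.43,14.86,1.09,1.48,0.16
5,membrane_bound,lattice_3d,77.20,0.49,15.10,1.10,1.32,0.17
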