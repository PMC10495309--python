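geometry,internalization,arrangement,b_init,b_init_sd,b_repair,b_repair_sd
1,internalized,planar_2d,163.10,1.82,145.36,1.90
1,membrane_bound,planar_2d,160.81,1.94,144.95,1.98
2,internalized,planar_2d,161.95,1.81,143.88,1.96
2,membrane_bound,planar_2d,161.97,1.91,144.90,2.04
3,internalized,planar_2d,157.35,1.74,137.71,1.75
3,membrane_bound,planar_2d,159.63,2.35,142.29,2.68
4,internalized,planar_2d,157.15,2.44,137.76,2.59
4,membrane_bound,planar_2d,163.13,2.37,143.89,2.47
5,internalized,planar_2d,160.69,2.36,141.67,2.51
5,membrane_bound,planar_2d,160.12,2.73,142.74,2.84
1,internalized,lattice_3d,166.60,1.16,152.99,1.23
1,membrane_bound,lattice_3d,166.96,1.13,154.34,1.20
2,internalized,lattice_3d,164.56,1.36,150.75,1.46
2,membrane_bound,lattice_3d,167.69,1.17,154.83,1.25
3,internalized,lattice_3d,169.71,1.32,156.25,1.39
3,membrane_bound,lattice_3d,165.86,1.30,152.59,1.36
4,internalized,lattice_3d,164.95,1.14,150.78,1.21
4,membrane_bound,lattice_3d,164.47,1.17,149.65,1.20
5,internalized,lattice_3d,164.49,1.32,150.94,1.40
5,membrane_bound,lattice_3d,165.55,1.34,152.14,1.40
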