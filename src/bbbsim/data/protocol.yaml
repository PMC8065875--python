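# Reference 3D T1-weighted spoiled-gradient-echo DCE protocol (1.5 T)
tr_s: 0.00824
te_s: 0.0031
flip_deg: 12.0
fov_mm: [240.0, 240.0, 184.0]
acquired_matrix: [256, 192, 46]   # 0.9375 x 1.25 x 4 mm voxels
temporal_resolution_s: 73.0
n_pre: 1
n_post: 20
r1_per_mM_s: 3.9      # gadoterate longitudinal relaxivity (assumed, configurable)
r2star_per_mM_s: 4.5  # effective transverse relaxivity (assumed, configurable)
snr_nawm: 91.5        # target spatial SNR in normal-appearing white matter
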