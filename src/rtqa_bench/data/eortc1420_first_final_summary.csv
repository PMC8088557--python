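structure,n,dsi_first_mean,dsi_first_sd,dsi_final_mean,dsi_final_sd,hd_first_mean,hd_first_sd,hd_final_mean,hd_final_sd
brainstem_prv,3,0.74,0.16,0.75,0.14,8.94,4.26,7.88,3.38
cervical_esophagus,4,0.49,0.10,0.33,0.16,27.22,11.98,18.83,8.44
cricopharyngeal_inlet,5,0.36,0.22,0.38,0.09,13.42,6.75,13.19,3.87
contralateral_submandibular,1,0.83,,0.83,,5.37,,5.37,
extended_oral_cavity,5,0.76,0.02,0.84,0.08,26.36,4.22,15.56,9.19
glottis,3,0.43,0.19,0.56,0.15,13.28,7.63,8.58,4.89
mandible,6,0.88,0.04,0.91,0.02,19.84,8.59,6.75,4.98
pharyngeal_constrictors,8,0.47,0.16,0.59,0.09,30.34,8.83,19.70,3.65
prophylactic_ptv,19,0.70,0.13,0.78,0.05,26.23,16.33,15.64,4.59
therapeutic_ptv,8,0.64,0.15,0.70,0.10,11.14,4.05,10.17,2.31
spinal_cord_prv,3,0.78,0.07,0.80,0.09,6.61,2.73,6.68,2.80
supraglottic_larynx,2,0.42,0.31,0.41,0.29,21.03,18.35,23.33,15.09
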