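structure,category,count
brainstem_prv,oar_delineation,3
cervical_esophagus,oar_delineation,4
cricopharyngeal_inlet,oar_delineation,5
contralateral_submandibular,oar_delineation,1
extended_oral_cavity,oar_delineation,5
glottis,oar_delineation,3
mandible,oar_delineation,6
pharyngeal_constrictors,oar_delineation,8
spinal_cord_prv,oar_delineation,3
supraglottic_larynx,oar_delineation,2
prophylactic_ptv,target_delineation,19
therapeutic_ptv,target_delineation,8
treatment_plan,planning,9
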