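record,compartment,total_volume_ml,vascular_ml,interstitial_ml,plasma_flow_ml_day,lymph_flow_ml_day,species,extravasation_per_day,lymph_exit_per_day
compartment,LUNGS,0.2,0.014,0.04,11126.253,22.253,,,
compartment,LIVER,1.3,0.091,0.26,2800.0,5.6,,,
compartment,GI,2.7,0.189,0.54,2300.0,4.6,,,
compartment,SPLEEN,0.1,0.007,0.02,140.0,0.28,,,
compartment,HEART,0.15,0.0105,0.03,470.0,0.94,,,
compartment,KIDNEYS,0.5,0.035,0.1,2200.0,4.4,,,
compartment,SKIN,2.9,0.203,0.58,1000.0,2.0,,,
compartment,MUSCLE,11.0,0.77,2.2,1600.0,3.2,,,
compartment,BONE,2.8,0.196,0.56,430.0,0.86,,,
compartment,LYMPH_NODES,0.25,0.0175,0.05,84.0,0.168,,,
compartment,TUMOR1,0.03,0.0021,0.015,40.0,0.08,,,
compartment,TUMOR2,0.03,0.0021,0.015,40.0,0.08,,,
compartment,ARTERIAL_BLOOD,0.6,0.6,0.0,0.0,0.0,,,
compartment,VENOUS_BLOOD,1.1,1.1,0.0,0.0,0.0,,,
transport,LUNGS,,,,,,DC,2.0,0.8
transport,LIVER,,,,,,DC,2.0,0.8
transport,GI,,,,,,DC,2.0,0.8
transport,SPLEEN,,,,,,DC,2.0,0.8
transport,HEART,,,,,,DC,2.0,0.8
transport,KIDNEYS,,,,,,DC,2.0,0.8
transport,SKIN,,,,,,DC,2.0,0.8
transport,MUSCLE,,,,,,DC,2.0,0.8
transport,BONE,,,,,,DC,2.0,0.8
transport,LYMPH_NODES,,,,,,DC,2.0,1.0
transport,TUMOR1,,,,,,DC,0.3,0.2
transport,TUMOR2,,,,,,DC,0.3,0.2
transport,LUNGS,,,,,,M1,2.0,0.8
transport,LIVER,,,,,,M1,2.0,0.8
transport,GI,,,,,,M1,2.0,0.8
transport,SPLEEN,,,,,,M1,2.0,0.8
transport,HEART,,,,,,M1,2.0,0.8
transport,KIDNEYS,,,,,,M1,2.0,0.8
transport,SKIN,,,,,,M1,2.0,0.8
transport,MUSCLE,,,,,,M1,2.0,0.8
transport,BONE,,,,,,M1,2.0,0.8
transport,LYMPH_NODES,,,,,,M1,2.0,1.0
transport,TUMOR1,,,,,,M1,0.3,0.2
transport,TUMOR2,,,,,,M1,0.3,0.2
transport,LUNGS,,,,,,M2,2.0,0.8
transport,LIVER,,,,,,M2,2.0,0.8
transport,GI,,,,,,M2,2.0,0.8
transport,SPLEEN,,,,,,M2,2.0,0.8
transport,HEART,,,,,,M2,2.0,0.8
transport,KIDNEYS,,,,,,M2,2.0,0.8
transport,SKIN,,,,,,M2,2.0,0.8
transport,MUSCLE,,,,,,M2,2.0,0.8
transport,BONE,,,,,,M2,2.0,0.8
transport,LYMPH_NODES,,,,,,M2,2.0,1.0
transport,TUMOR1,,,,,,M2,0.3,0.2
transport,TUMOR2,,,,,,M2,0.3,0.2
transport,LUNGS,,,,,,TREG,2.5,0.8
transport,LIVER,,,,,,TREG,2.5,0.8
transport,GI,,,,,,TREG,2.5,0.8
transport,SPLEEN,,,,,,TREG,2.5,0.8
transport,HEART,,,,,,TREG,2.5,0.8
transport,KIDNEYS,,,,,,TREG,2.5,0.8
transport,SKIN,,,,,,TREG,2.5,0.8
transport,MUSCLE,,,,,,TREG,2.5,0.8
transport,BONE,,,,,,TREG,2.5,0.8
transport,LYMPH_NODES,,,,,,TREG,2.5,1.0
transport,TUMOR1,,,,,,TREG,0.3,0.2
transport,TUMOR2,,,,,,TREG,0.3,0.2
transport,LUNGS,,,,,,TE1,3.0,0.8
transport,LIVER,,,,,,TE1,3.0,0.8
transport,GI,,,,,,TE1,3.0,0.8
transport,SPLEEN,,,,,,TE1,3.0,0.8
transport,HEART,,,,,,TE1,3.0,0.8
transport,KIDNEYS,,,,,,TE1,3.0,0.8
transport,SKIN,,,,,,TE1,3.0,0.8
transport,MUSCLE,,,,,,TE1,3.0,0.8
transport,BONE,,,,,,TE1,3.0,0.8
transport,LYMPH_NODES,,,,,,TE1,3.0,1.0
transport,TUMOR1,,,,,,TE1,0.4,0.2
transport,TUMOR2,,,,,,TE1,0.4,0.2
transport,LUNGS,,,,,,APC,1.5,0.8
transport,LIVER,,,,,,APC,1.5,0.8
transport,GI,,,,,,APC,1.5,0.8
transport,SPLEEN,,,,,,APC,1.5,0.8
transport,HEART,,,,,,APC,1.5,0.8
transport,KIDNEYS,,,,,,APC,1.5,0.8
transport,SKIN,,,,,,APC,1.5,0.8
transport,MUSCLE,,,,,,APC,1.5,0.8
transport,BONE,,,,,,APC,1.5,0.8
transport,LYMPH_NODES,,,,,,APC,1.5,1.0
transport,TUMOR1,,,,,,APC,0.3,1.0
transport,TUMOR2,,,,,,APC,0.3,1.0
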