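,age,prefx,wmsa,cortical_thickness,assoc_segregation,sm_segregation,episodic_memory,processing_speed,verbal_fluency,working_memory,reasoning,verbal_ability
age,1.000,-0.381,0.427,-0.629,-0.707,-0.425,-0.454,-0.091,0.131,-0.223,-0.601,0.415
prefx,-0.381,1.000,-0.314,0.154,0.525,0.211,0.234,-0.048,0.140,0.045,0.092,-0.182
wmsa,0.427,-0.314,1.000,-0.326,-0.378,-0.383,-0.168,-0.295,0.097,-0.263,-0.313,0.283
cortical_thickness,-0.629,0.154,-0.326,1.000,0.563,0.346,0.392,0.181,-0.070,0.269,0.437,-0.157
assoc_segregation,-0.707,0.525,-0.378,0.563,1.000,0.504,0.450,0.184,0.047,0.196,0.529,-0.280
sm_segregation,-0.425,0.211,-0.383,0.346,0.504,1.000,0.251,0.322,0.209,0.442,0.404,-0.087
episodic_memory,-0.454,0.234,-0.168,0.392,0.450,0.251,1.000,0.334,0.008,0.345,0.431,0.070
processing_speed,-0.091,-0.048,-0.295,0.181,0.184,0.322,0.334,1.000,0.249,0.565,0.294,-0.140
verbal_fluency,0.131,0.140,0.097,-0.070,0.047,0.209,0.008,0.249,1.000,0.248,-0.085,0.162
working_memory,-0.223,0.045,-0.263,0.269,0.196,0.442,0.345,0.565,0.248,1.000,0.498,0.187
reasoning,-0.601,0.092,-0.313,0.437,0.529,0.404,0.431,0.294,-0.085,0.498,1.000,0.061
verbal_ability,0.415,-0.182,0.283,-0.157,-0.280,-0.087,0.070,-0.140,0.162,0.187,0.061,1.000
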