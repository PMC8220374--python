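com_offsets:
- 0.28215562161653507
- 0.28215562161653507
- 0.144659582060075
- 0.2708027376164604
foot_geometry:
- 0.0575
- 0.115
- 0.0575
foot_length: 0.23
foot_mass: 2.3200000000000003
g: 9.81
inertias:
- 0.1535334421460276
- 0.3301794454753282
- 0.15680845081558822
- 0.9584739658313116
joint_angle_limits:
- - -0.7
  - 0.7
- - -2.2
  - 0.05
- - -0.7
  - 2.1
- - -1.0
  - 1.0
joint_torque_limits:
- - -220.0
  - 220.0
- - -280.0
  - 280.0
- - -360.0
  - 360.0
- - -200.0
  - 200.0
kind: DOF4
segment_lengths:
- 0.49762896228665804
- 0.49762896228665804
- 0.28931916412015
- 0.601783861369912
segment_masses:
- 7.4399999999999995
- 16.0
- 22.480000000000004
- 31.76
standing_com_height: 1.12
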