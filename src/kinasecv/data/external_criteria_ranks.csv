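compound,helix_displacement_rank,salt_bridge_rank
C4481,6,5
C19005,3,8
C11596,8,7
C7806,1,1
C7826,11,9
C7831,4,3
C7819,10,10
C12690,9,4
C4049,2,2
C19017,7,6
EAI001,5,11
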