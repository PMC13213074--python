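compound,ml_score_rank,helix_displacement_rank,salt_bridge_rank,mmgbsa_rank,docking_rank
C4481,1,6,5,3,4
C19005,2,3,8,6,8
C11596,3,8,7,1,2
C7806,4,1,1,5,7
C7826,5,11,9,10,5
C7831,6,4,3,2,9
C7819,7,10,10,7,10
C12690,8,9,4,9,11
C4049,9,2,2,4,3
C19017,10,7,6,8,6
EAI001,11,5,11,11,1
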