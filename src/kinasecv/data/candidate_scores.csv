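compound,ml_score,docking_score
C4481,9.61,-7.2
C19005,9.54,-6.4
C11596,9.34,-7.4
C7806,9.34,-6.5
C7826,9.34,-7.0
C7831,9.34,-6.1
C7819,9.32,-5.9
C12690,9.31,-4.7
C4049,9.30,-7.3
C19017,9.27,-6.7
EAI001,6.32,-9.9
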