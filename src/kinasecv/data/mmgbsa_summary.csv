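compound,VDW,EEL,EGB,ESURF,dG_gas,dG_solv,dG_total,sd
C11596,-68.35,-19.64,45.48,-8.25,-87.99,37.23,-50.76,3.97
C7831,-66.32,-35.91,60.01,-7.70,-102.23,52.31,-49.92,3.88
C4481,-69.80,-8.29,35.49,-7.27,-78.10,28.21,-49.83,2.91
C4049,-60.42,-50.05,69.13,-7.13,-110.48,62.0,-48.47,3.07
C7806,-66.0,-29.38,56.59,-8.10,-95.38,48.49,-46.89,3.62
C19005,-63.78,-14.65,38.84,-7.21,-78.43,31.62,-46.81,3.14
C7819,-59.16,-15.05,36.62,-7.52,-74.22,29.10,-45.12,4.38
C19017,-59.20,-12.19,37.96,-6.82,-71.36,31.14,-40.21,3.19
C12690,-52.66,-4.27,25.85,-6.58,-56.93,19.26,-37.66,2.90
C7826,-53.27,-9.75,32.20,-6.82,-63.03,25.38,-37.65,4.80
EAI001,-49.54,-17.52,37.99,-6.06,-67.06,31.93,-35.12,2.85
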