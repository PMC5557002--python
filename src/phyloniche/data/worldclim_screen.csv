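variable,mean_auc,ALT,Bio1,Bio2,Bio3,Bio4,Bio5,Bio6,Bio7,Bio8,Bio9,Bio10,Bio11,Bio12,Bio13,Bio14,Bio15,Bio16,Bio17,Bio18,Bio19
ALT,0.79,1,,,,,,,,,,,,,,,,,,,
Bio1,0.77,-0.08,1,,,,,,,,,,,,,,,,,,
Bio2,0.81,-0.16,-0.54,1,,,,,,,,,,,,,,,,,
Bio3,0.85,0.31,0.83,-0.63,1,,,,,,,,,,,,,,,,
Bio4,0.84,-0.31,-0.89,0.66,-0.96,1,,,,,,,,,,,,,,,
Bio5,0.87,-0.79,0.17,0.46,-0.29,0.27,1,,,,,,,,,,,,,,
Bio6,0.83,0.11,0.96,-0.68,0.93,-0.97,-0.09,1,,,,,,,,,,,,,
Bio7,0.91,-0.28,-0.88,0.75,-0.95,0.99,0.31,-0.97,1,,,,,,,,,,,,
Bio8,0.82,-0.21,0.60,-0.40,0.41,-0.47,0.19,0.55,-0.48,1,,,,,,,,,,,
Bio9,0.81,0.01,0.89,-0.45,0.77,-0.83,0.07,0.87,-0.82,0.27,1,,,,,,,,,,
Bio10,0.84,-0.77,0.55,0.02,0.07,-0.11,0.87,0.32,-0.11,0.43,0.42,1,,,,,,,,,
Bio11,0.82,0.11,0.98,-0.62,0.92,-0.97,-0.04,1.00,-0.96,0.55,0.89,0.35,1,,,,,,,,
Bio12,0.86,0.18,0.59,-0.61,0.73,-0.68,-0.25,0.68,-0.70,0.22,0.59,0.06,0.65,1,,,,,,,
Bio13,0.83,0.27,0.65,-0.59,0.71,-0.73,-0.22,0.72,-0.74,0.32,0.60,0.08,0.71,0.88,1,,,,,,
Bio14,0.89,-0.06,0.25,-0.39,0.43,-0.29,-0.18,0.32,-0.35,-0.01,0.33,0.04,0.28,0.71,0.36,1,,,,,
Bio15,0.87,0.24,0.46,-0.16,0.32,-0.46,0.03,0.43,-0.40,0.42,0.31,0.14,0.46,-0.02,0.38,-0.57,1,,,,
Bio16,0.83,0.26,0.66,-0.60,0.72,-0.74,-0.23,0.73,-0.75,0.33,0.61,0.08,0.72,0.91,0.99,0.41,0.34,1,,,
Bio17,0.93,-0.06,0.28,-0.41,0.45,-0.31,-0.17,0.35,-0.37,-0.01,0.35,0.06,0.31,0.74,0.38,0.99,-0.56,0.43,1,,
Bio18,0.84,0.25,0.52,-0.56,0.59,-0.60,-0.32,0.59,-0.63,0.35,0.45,0.02,0.57,0.72,0.68,0.45,0.18,0.72,0.47,1,
Bio19,0.87,-0.01,0.42,-0.42,0.56,-0.45,-0.10,0.48,-0.49,0.08,0.47,0.12,0.45,0.84,0.67,0.77,-0.25,0.69,0.79,0.40,1
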