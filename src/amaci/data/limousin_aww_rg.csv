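,direct_CZE,direct_DFS,direct_ESP,direct_GBR,direct_IRL,direct_FRA,direct_DEU,direct_CHE,maternal_CZE,maternal_DFS,maternal_ESP,maternal_GBR,maternal_IRL,maternal_FRA,maternal_DEU,maternal_CHE
direct_CZE,0.24,0.16,0.21,0.15,0.19,0.12,0.14,0.22,0.1,0.15,0.2,0.16,0.16,0.1,0.12,0.19
direct_DFS,0.87,0.3,0.16,0.1,0.13,0.07,0.1,0.15,0.13,0.06,0.14,0.11,0.12,0.06,0.09,0.16
direct_ESP,0.74,0.77,0.13,0.17,0.2,0.14,0.17,0.22,0.2,0.18,0.16,0.16,0.16,0.1,0.15,0.22
direct_GBR,0.71,0.82,0.94,0.29,0.14,0.06,0.1,0.18,0.15,0.12,0.15,0.06,0.11,0.06,0.11,0.18
direct_IRL,0.83,0.76,0.87,0.91,0.35,0.11,0.13,0.21,0.16,0.15,0.18,0.11,0.14,0.09,0.12,0.2
direct_FRA,0.76,0.89,0.77,0.82,0.76,0.29,0.06,0.13,0.09,0.08,0.1,0.08,0.1,0.02,0.06,0.12
direct_DEU,0.76,0.94,0.76,0.77,0.62,0.81,0.24,0.14,0.13,0.11,0.16,0.13,0.13,0.06,0.05,0.15
direct_CHE,0.85,0.81,0.76,0.71,0.7,0.7,0.7,0.12,0.19,0.18,0.23,0.2,0.19,0.11,0.14,0.1
maternal_CZE,-0.12,0.04,0.07,0.12,-0.01,-0.1,0.08,0.01,0.18,0.2,0.26,0.21,0.22,0.14,0.16,0.27
maternal_DFS,-0.05,-0.14,0.02,-0.01,-0.02,-0.11,-0.07,-0.01,0.68,0.14,0.23,0.18,0.19,0.11,0.14,0.24
maternal_ESP,0.03,0.09,-0.22,-0.08,-0.09,-0.05,0.05,0.02,0.67,0.68,0.07,0.24,0.25,0.15,0.21,0.33
maternal_GBR,0.14,0.06,-0.03,-0.1,-0.03,-0.14,0.07,0.08,0.79,0.69,0.7,0.07,0.18,0.12,0.16,0.26
maternal_IRL,-0.03,0.07,-0.06,-0.05,-0.19,-0.12,0.12,0.11,0.69,0.68,0.81,0.72,0.17,0.16,0.16,0.24
maternal_FRA,-0.02,-0.05,-0.03,-0.06,-0.09,-0.33,-0.01,0.08,0.85,0.69,0.71,0.87,0.82,0.09,0.07,0.17
maternal_DEU,-0.02,-0.09,-0.03,-0.01,0.06,-0.1,-0.24,0.09,0.68,0.68,0.67,0.69,0.68,0.69,0.2,0.2
maternal_CHE,0.12,0.11,0.07,0.08,0.03,-0.05,0.06,0.4,0.73,0.68,0.67,0.66,0.65,0.77,0.66,0.05
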