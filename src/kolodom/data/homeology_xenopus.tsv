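diploid	tetraploid_L	tetraploid_S
Chr01	chr1L	chr1S
Chr02	chr2L	chr2S
Chr03	chr3L	chr3S
Chr04	chr4L	chr4S
Chr05	chr5L	chr5S
Chr06	chr6L	chr6S
Chr07	chr7L	chr7S
Chr08	chr8L	chr8S
Chr09	chr9_10L	chr9_10S
Chr10	chr9_10L	chr9_10S
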