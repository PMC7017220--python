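>armadillidin_CE synthetic assay peptide, Chaetophiloscia elongata armadillidin
TPGRPYYGGGYNGGYRGGYRRGGGFYGGGRFYGGGEGYRGGYYRGYRG
>armadillidin_PP synthetic assay peptide, Porcellionides pruinosus armadillidin
SYGRGSYGGGSIGRGSFGHGGGSFGRGGGRFGHGGGRFGGIGGGGRYGGGHIGGYRG
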