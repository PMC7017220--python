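>A_assimile Armadillidium assimile mature armadillidin
GHIRRPYIGGGGLYGGGGGFHRGGGFHRGGGGFIGGGGFHRGGGFNRGGSYGYNG
>A_depressum Armadillidium depressum mature armadillidin
GGFGRPYIGGGGFNRGGGLHRGGGFNSGGGFNRGGGFNRGGGFNRGGGFHRGGSFGYNG
>A_maculatum Armadillidium maculatum mature armadillidin
GGFGRPYIGGGGFNRGGGFHRGGGFRSGGGFHRGGGFNRGGGFHRGGSYGYNG
>A_nasatum Armadillidium nasatum mature armadillidin
GHIGRPYIGGGGGGIYRGGGFRTGGGFRTGGGFHRGGGGFHRGGGFHRGGSYGYNG
>A_tunisiense Armadillidium tunisiense mature armadillidin
GHIGRPYIGGGGIYRGGGFRTGGGFHRGGGFHRGGGFQRGGGFYGGGSYGYNG
>A_versicolor Armadillidium versicolor mature armadillidin
GGFGRPYIGGGGFNRGGGFHRGGGFNRGGGFHRGGGFNRGGGFHRGGSFGYNG
>A_vulgare_H Armadillidium vulgare mature armadillidin, H variant
GHLGRPYIGGGGGFNRGGGFHRGGGFHRGGGFHSGGGFHRGGGFHSGGSFGYR
>A_vulgare_Q Armadillidium vulgare mature armadillidin, Q variant
GHLGRPYIGGGGGFNRGGGFHRGGGFHRGGGFQSGGGFHRGGGFHSGGSFGYR
>A_officinalis Armadillo officinalis mature armadillidin
TFKPCGRSSGGSRCNRGYNRGIIGISGGNNKINGGGDFDDDDYESDYEDYNNGIIGIRG
GTNTVNGGGSNNPKDSALKDYNNGIIGIGGGTNTVNGGGSNNPKDSAFKDPRGNRGIIG
ISGGRNVVQRG
>C_elongata Chaetophiloscia elongata mature armadillidin
TPGRPYYGGGYNGGYRGGYRRGGGFYGGGRFYGGGEGYRGGYYRGYRG
>E_purpurascens Eluma purpurascens mature armadillidin
SYVRRPYIGGGGGGFHRGGGFHRGGGFISGGGFHRGGGFNRGGGYGYNG
>P_dilatatus Porcellio dilatatus dilatatus mature armadillidin
GHHGYGGSYGGRRYGHGGGRFGGIRGGGYGGGGHIGGGYGGYGGYRG
>P_dispar Porcellio dispar mature armadillidin
GYIRKPYIGRGYGGGGYHRGGGFGYGGGYYRGGVGYGGGGYGGYGYRG
>P_laevis Porcellio laevis mature armadillidin
SFIRKPYIGGGYGGYRGGGGYGGYRGGYYRGGGHYGGGYGGYGYRG
>P_muscorum Philoscia muscorum mature armadillidin
TFGRPYYGGGFNRGFGGGYHRGGGFHRGGGFYGGGFRGGYNRGYLG
>P_pruinosus Porcellionides pruinosus mature armadillidin
SYGRGSYGGGSIGRGSFGHGGGSFGRGGGRFGHGGGRFGGIGGGGRYGGGHIGGYRG
>P_scaber Porcellio scaber mature armadillidin
GYIRRPVGYYGGGGGRYGGGRFGGGGGGIGGGRYGGGGRYGGGSYGGYHG
>O_asellus Oniscus asellus mature armadillidin
TYRPSYGGGGGFNRGGGRGGGIHRGGGIGGGIYRGGGIGGGHRGGGGGRFNRGYGYR
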