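{
  "comment": "Built-in cyclodextrin registry. n_glucose: macrocycle glucopyranose count. fragment: H-terminated primary-face side-chain fragment SMILES (native C-6 hydroxymethyl group reads as methanol, CO). degree_of_substitution: average substituents per glucose unit across all hydroxyl positions. dataset_weight: relative abundance of each CD type in curated stability-constant collections, used by the synthetic generator.",
  "entries": [
    {"name": "alphaCD", "aliases": ["aCD", "αCD", "alpha-CD", "alpha-cyclodextrin"], "n_glucose": 6, "fragment": "CO", "degree_of_substitution": 0.0, "dataset_weight": 411},
    {"name": "carboxyl-alphaCD", "aliases": ["carboxyl αCD", "carboxyl-aCD"], "n_glucose": 6, "fragment": "OC=O", "degree_of_substitution": 1.0, "dataset_weight": 1},
    {"name": "hydroxypropyl-alphaCD", "aliases": ["HP-aCD", "HP-αCD", "hydroxypropyl-αCD", "2-hydroxypropyl-alpha-cyclodextrin"], "n_glucose": 6, "fragment": "COCC(C)O", "degree_of_substitution": 0.6, "dataset_weight": 3},
    {"name": "trimethyl-alphaCD", "aliases": ["TM-aCD", "trimethyl-αCD"], "n_glucose": 6, "fragment": "COC", "degree_of_substitution": 3.0, "dataset_weight": 8},
    {"name": "betaCD", "aliases": ["bCD", "βCD", "beta-CD", "beta-cyclodextrin"], "n_glucose": 7, "fragment": "CO", "degree_of_substitution": 0.0, "dataset_weight": 638},
    {"name": "acetyl-betaCD", "aliases": ["acetyl-βCD", "Ac-bCD"], "n_glucose": 7, "fragment": "COC(C)=O", "degree_of_substitution": 1.0, "dataset_weight": 19},
    {"name": "carboxyl-betaCD", "aliases": ["carboxyl-βCD"], "n_glucose": 7, "fragment": "OC=O", "degree_of_substitution": 1.0, "dataset_weight": 15},
    {"name": "dimethyl-betaCD", "aliases": ["DM-bCD", "dimethyl-βCD", "DIMEB"], "n_glucose": 7, "fragment": "COC", "degree_of_substitution": 2.0, "dataset_weight": 52},
    {"name": "hydroxypropyl-betaCD", "aliases": ["HP-bCD", "HP-βCD", "hydroxypropyl-βCD", "2-hydroxypropyl-beta-cyclodextrin", "HPBCD"], "n_glucose": 7, "fragment": "COCC(C)O", "degree_of_substitution": 0.65, "dataset_weight": 136},
    {"name": "methyl-betaCD", "aliases": ["methyl-βCD", "randomly methylated-βCD", "randomly methylated-betaCD", "RM-bCD", "RAMEB"], "n_glucose": 7, "fragment": "COC", "degree_of_substitution": 1.8, "dataset_weight": 49},
    {"name": "betaCD-sulfate", "aliases": ["βCD sulfate", "bCD sulfate"], "n_glucose": 7, "fragment": "COS(O)(=O)=O", "degree_of_substitution": 1.0, "dataset_weight": 16},
    {"name": "sulfobutylether-betaCD", "aliases": ["SBE-bCD", "sulfobutyl ether βCD", "sulfobutyl ether betaCD", "SBECD"], "n_glucose": 7, "fragment": "COCCCCS(O)(=O)=O", "degree_of_substitution": 0.9, "dataset_weight": 117},
    {"name": "succinate-betaCD", "aliases": ["succinate-βCD"], "n_glucose": 7, "fragment": "COC(=O)CCC(O)=O", "degree_of_substitution": 1.0, "dataset_weight": 5},
    {"name": "trimethyl-betaCD", "aliases": ["TM-bCD", "trimethyl-βCD", "TRIMEB"], "n_glucose": 7, "fragment": "COC", "degree_of_substitution": 3.0, "dataset_weight": 19},
    {"name": "gammaCD", "aliases": ["gCD", "γCD", "gamma-CD", "gamma-cyclodextrin"], "n_glucose": 8, "fragment": "CO", "degree_of_substitution": 0.0, "dataset_weight": 160},
    {"name": "hydroxypropyl-gammaCD", "aliases": ["HP-gCD", "HP-γCD", "hydroxypropyl-γCD"], "n_glucose": 8, "fragment": "COCC(C)O", "degree_of_substitution": 0.6, "dataset_weight": 5}
  ]
}
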