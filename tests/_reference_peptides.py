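"""Published reference peptide set used as ground truth in tests.

Each entry: (name, score_type, sequence, published_score, block_split, mw).
``block_split`` is the published hydrophobic/hydrophilic divide position
(gamma peptides only, 1-based); ``mw`` is the published average molecular
weight in g/mol.
"""

REFERENCE_PEPTIDES = [
    ("alpha-10", "alpha", "KKPVSKDSPETYEEALKRFAKLLSDRKKL", 2.176, None, 3405.9),
    ("alpha-11", "alpha", "EALKRFAKLLSD", 3.522, None, 1390.6),
    ("alpha-12", "alpha", "DSPETYEEALKRFAKLLSD", 3.037, None, 2212.4),
    ("alpha-13", "alpha", "NRPFAAAKDIVPFYFEHGPHIFN", 2.155, None, 2688.0),
    ("alpha-14", "alpha", "AKDIVPFYFEHGPHIFN", 2.255, None, 2031.3),
    ("alpha-15", "alpha", "IPATILEFLEGQLQEVDNN", 2.000, None, 2143.4),
    ("alpha-16", "alpha", "ILEFLEGQLQEVDN", 2.978, None, 1646.8),
    ("alpha-17", "alpha", "KYDGKYLMQVLQE", 2.029, None, 1614.9),
    ("alpha-18", "alpha", "KYLMQVLQEKLGE", 2.022, None, 1578.9),
    ("alpha-19", "alpha", "KYLMQVLQEKL", 2.058, None, 1392.7),
    ("beta-20", "beta", "ELDSRLSYRIISTFWGALGGDVYLGKSPN", 2.630, None, 3215.6),
    ("beta-21", "beta", "ELDSRLSYRIISTFWGALGGDVYL", 3.131, None, 2732.0),
    ("beta-22", "beta", "CPFSSDDQFCLKVGV", 2.501, None, 1644.9),
    ("beta-23", "beta", "FIPLSTNIFEDQLLNIQFNIPT", 2.391, None, 2577.9),
    ("beta-24", "beta", "LNIQFNI", 4.066, None, 861.0),
    ("beta-26", "beta", "GKELDPRLSYRI", 2.218, None, 1446.7),
    ("beta-27", "beta", "LNIQFNIPTPKLC", 2.213, None, 1500.8),
    ("beta-28", "beta", "VHQNGKRRLALVKDNPLDVSFK", 2.056, None, 2534.9),
    ("beta-29", "beta", "IGSSSHFGPHIFEGELLNIQFDIS", 2.027, None, 2644.9),
    ("beta-30", "beta", "DDNFCAKVGVVIQ", 2.016, None, 1407.6),
    ("beta-31", "beta", "LGGDVYLGKSPNSDAPCP", 2.011, None, 1789.9),
    ("gamma-1", "gamma", "GIKGIIPAIILEFLEGQLQEVDNNKDAR", 4.146, 14, 3094.5),
    ("gamma-34", "gamma", "CRDDNFCAKVGVVI", 3.387, 5, 1538.8),
    ("gamma-35", "gamma", "RDDNFCAKVGVVI", 3.933, 4, 1435.7),
    ("gamma-36", "gamma", "FDVIGGTSTGGLLTAMITTPNENNRP", 3.190, 17, 2676.9),
    ("gamma-37", "gamma", "LLTAMITTPNENNRP", 4.037, 6, 1684.9),
    ("gamma-38", "gamma", "FCLKVGVVHQNGKRRLALVKDNP", 3.168, 8, 2592.1),
    ("gamma-39", "gamma", "HQNGKRRLALV", 4.790, 7, 1291.5),
    ("gamma-40", "gamma", "SSDDQFCLKVGVV", 3.137, 5, 1396.6),
    ("gamma-41", "gamma", "KDNPETYEEALKRFAKLLS", 3.066, 13, 2252.5),
    ("gamma-42", "gamma", "DTNGKELNPNSSYRIISIGRGALGGDVYL", 3.055, 14, 3080.4),
    ("gamma-43", "gamma", "NPNSSYRIISI", 3.401, 7, 1263.4),
    ("gamma-44", "gamma", "DNFCAKVGVVIQNGKRR", 3.044, 11, 1904.2),
    ("gamma-45", "gamma", "VGVVIQNGKRR", 4.779, 5, 1225.5),
    ("gamma-46", "gamma", "FAKLLSDRKKLRANK", 3.043, 5, 1788.2),
    ("gamma-47", "gamma", "TPNENNRPFAAAKDIV", 3.024, 8, 1756.9),
    ("gamma-48", "gamma", "GIIPATILEFLEGQLQEVDNN", 3.003, 11, 2313.6),
    ("gamma-49", "gamma", "FCLKVGVIHQNGKRRLALVK", 2.478, 8, 2279.8),
]

GAMMA_PEPTIDES = [r for r in REFERENCE_PEPTIDES if r[1] == "gamma"]
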