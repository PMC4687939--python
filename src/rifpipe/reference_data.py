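"""Published worked-example inputs.

Published group-mean *Biceps femoris* intramuscular fatty-acid
composition (g/100 g total fatty acids) of newborn purebred Iberian (IB)
and Iberian x Duroc (IBxDU) piglets.  These serve as ready-made inputs
for the phenotype indices and the synthetic fatty-acid generator.
"""

# fatty acid -> (IBxDU mean, IB mean)
PIGLET_BF_FATTY_ACIDS: dict[str, tuple[float, float]] = {
    "C12:0": (0.65, 0.58),
    "C14:0": (2.57, 2.32),
    "C15:1": (1.28, 1.18),
    "C16:0": (25.90, 25.44),
    "C16:1 n-9": (1.90, 2.09),
    "C16:1 n-7": (5.38, 4.57),
    "C17:0": (1.69, 1.44),
    "C17:1": (0.91, 0.81),
    "C18:0": (10.85, 9.96),
    "C18:1 n-9": (23.80, 25.82),
    "C18:1 n-7": (6.15, 5.69),
    "C18:2 n-6": (7.31, 9.17),
    "C20:1 n-9": (0.53, 0.53),
    "C20:2 n-6": (0.41, 0.40),
    "C20:3 n-6": (0.62, 0.55),
    "C20:4 n-6": (6.31, 5.99),
    "C22:1 n-9": (1.21, 1.08),
    "C22:4 n-6": (1.58, 1.27),
    "C22:5 n-3": (0.48, 0.50),
    "C22:6 n-3": (0.67, 0.62),
}


def piglet_fatty_acid_means(group: str) -> dict[str, float]:
    """Printed fatty-acid group means for ``group`` in {"IB", "IBxDU"}."""
    idx = {"IBxDU": 0, "IB": 1}[group]
    return {name: vals[idx] for name, vals in PIGLET_BF_FATTY_ACIDS.items()}
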