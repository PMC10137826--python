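"""The five published key miRNA pairs, shipped as a predictor schema.

These pairs were selected on the original microarray + qPCR cohorts and
are provided so a user can retrain or apply a model with the published
feature schema to their own measurements of the ten miRNAs. Reproducing
the selection itself requires the original cohorts.
"""

PUBLISHED_KEY_PAIRS: list[str] = [
    "miR-133b|miR-597-5p",
    "miR-143-3p|miR-214-3p",
    "miR-224-5p|miR-345-5p",
    "miR-433-3p|miR-497-5p",
    "miR-576-3p|miR-596",
]

PUBLISHED_MIRNAS: list[str] = sorted(
    {m for pair in PUBLISHED_KEY_PAIRS for m in pair.split("|")}
)
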