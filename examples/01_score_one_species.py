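"""Score one species' paired gonadal expression data.

Builds a tiny three-transcript expression matrix with two curated
intersexual/ovary sample pairs, computes per-pair IO-ratios, labels each
pair against the 5-fold cutoff, and prints the per-transcript IO-scores.
"""

import pandas as pd

import ioscore as io

expr = io.ExpressionMatrix(
    species="wrasse",
    data=pd.DataFrame(
        {
            "intersex_1": [52.0, 0.4, 3.0],
            "ovary_1": [1.0, 6.0, 2.9],
            "intersex_2": [40.0, 0.5, 3.2],
            "ovary_2": [0.8, 7.5, 3.1],
        },
        index=pd.Index(["amh_like", "cyp19a1a_like", "control"], name="transcript_id"),
    ),
)
manifest = pd.DataFrame(
    [
        ("wrasse", "pair1", "intersex_1", "ovary_1"),
        ("wrasse", "pair2", "intersex_2", "ovary_2"),
    ],
    columns=["species", "pair_id", "intersexual_sample", "ovary_sample"],
)

table = io.score_species(expr, manifest)
print(table.ratios.to_string(index=False))
print()
print(table.scores.to_string())
print()
print(
    "IO-score = pairs above 5-fold minus pairs below 0.2-fold: "
    "+2 means both pairs call the transcript up in the transitional gonad, "
    "-2 both call it down, 0 no consistent change."
)
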