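"""Refine the unsure variant set with the joint logistic-regression model.

Trains the two submodels (L1 on quality features, L2 on one-hot sequence
features) on the positive/negative sets, reports the held-out AUC, then
applies the joint decision rule P = 1/2 * sum w*P (w = 1 when a submodel
probability reaches 0.5) to the unsure set to expand the final call set.
"""

import tempfile
from pathlib import Path

from pyfaidx import Fasta

from resa import metrics, pipeline, simulate

with tempfile.TemporaryDirectory() as tmp:
    paths, cohort = simulate.end_to_end_fixture("default", Path(tmp), seed=1)
    result = pipeline.run_cohort_files(
        paths["manifest"], paths["exons_bed"],
        editing=paths["editing_tsv"], germline=[paths["germline_tsv"]],
    )
    refined = pipeline.refine_cohort(result.labeling, Fasta(str(paths["fasta"])))

    truth = cohort.truth.keys_of("somatic")
    core = set(result.labeling.keys_with("positive"))
    ev_core = metrics.evaluate_against_truth(core, truth)
    ev_final = metrics.evaluate_against_truth(set(refined.final), truth)

    print(f"held-out test AUC of the joint model: {refined.model.test_auc:.3f}")
    print(f"unsure keys classified positive and added: {len(refined.refined_keys)}")
    print(
        f"core:  precision={ev_core.precision:.3f} sensitivity={ev_core.sensitivity:.3f} "
        f"F0.5={ev_core.f_half:.3f}"
    )
    print(
        f"final: precision={ev_final.precision:.3f} sensitivity={ev_final.sensitivity:.3f} "
        f"F0.5={ev_final.f_half:.3f}"
    )
    print(
        "-> refinement recovers true somatic SNVs whose recurrence fell below the "
        "core filter's floor, raising sensitivity while precision stays high."
    )
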