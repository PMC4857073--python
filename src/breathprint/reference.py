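"""Published confusion matrices from the reference clinical study.

The proof-of-concept e-nose study of chronic liver disease that this
package's analysis design follows did not deposit patient-level data, but
it printed the held-out confusion matrices of its three PLS-DA models.
They are reproduced here as replication fixtures: collapsing them with
:func:`breathprint.diagnostics.collapse` and applying
:func:`breathprint.diagnostics.binary_metrics` recovers the study's
quoted sensitivity / specificity / likelihood-ratio / predictive-value
bullets at one-decimal precision.

Notes
-----
* ``disease_stage``: liver cirrhosis (LC) vs non-cirrhotic chronic liver
  disease (NC_CLD) vs healthy controls (CTRL), whole cohort.
* ``child_pugh``: Child-Pugh classes A/B/C within cirrhosis.  Its row
  totals (22/26/17) differ by one subject from the demographics table's
  class counts (21/27/17); the matrix is taken as authoritative for
  metric replication.
* ``aetiology``: infective vs non-infective disease after excluding 10
  mixed-aetiology and then 13 encephalopathic subjects.
* The two-class LC-vs-NC_CLD accuracies quoted "among patients with CLD"
  only back-calculate when subjects the 3-class model predicted CTRL are
  excluded — i.e. ``collapse(..., restrict_predicted=("LC", "NC_CLD"))``.
"""

from .diagnostics import ConfusionMatrix

__all__ = ["REFERENCE_CONFUSION"]

REFERENCE_CONFUSION: dict[str, ConfusionMatrix] = {
    "disease_stage": ConfusionMatrix(
        class_labels=("LC", "NC_CLD", "CTRL"),
        counts=[[49, 7, 9], [12, 27, 0], [0, 1, 55]],
    ),
    "child_pugh": ConfusionMatrix(
        class_labels=("A", "B", "C"),
        counts=[[15, 4, 3], [8, 15, 3], [4, 2, 11]],
    ),
    "aetiology": ConfusionMatrix(
        class_labels=("infective", "non_infective"),
        counts=[[9, 22], [6, 44]],
    ),
}
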