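"""Published contingency tables of the reference CAD study, as inputs.

These constants carry the printed per-cohort counts — the (3D call, 2D call)
cross-tabulations and the size-stratified detection counts — so the
diagnostics layer can recompute the reported sensitivities, specificities,
accuracies and likelihood ratios from raw counts.  They are data, not
expected values: every derived statistic is recomputed by the package.

Cohorts: a local validation set (109 PCs / 147 controls) and a nationwide
test set (671 PCs / 805 controls after one segmentation-failure exclusion).
"""

from .diagnostics import CrossTab

#: Nationwide test set cross-tab, cells (3D+,2D+), (3D+,2D-), (3D-,2D+), (3D-,2D-).
NATIONWIDE_CROSSTAB = CrossTab(pc=(498, 36, 80, 57),
                               control=(39, 25, 104, 637))

#: Local validation set cross-tab, same cell order.
LOCAL_CROSSTAB = CrossTab(pc=(80, 4, 12, 13),
                          control=(3, 4, 12, 128))

#: Nationwide detected/total PC counts per tumor-size stratum, per analysis.
NATIONWIDE_SIZE_STRATA = {
    "3d": {"<2cm": (48, 92), "2-4cm": (301, 380), ">4cm": (185, 199)},
    "2d": {"<2cm": (43, 92), "2-4cm": (341, 380), ">4cm": (194, 199)},
    "combined": {"<2cm": (65, 92), "2-4cm": (355, 380), ">4cm": (196, 199)},
}

#: Local validation detected/total PC counts per tumor-size stratum.
LOCAL_SIZE_STRATA = {
    "3d": {"<2cm": (12, 25), "2-4cm": (47, 59), ">4cm": (25, 25)},
    "2d": {"<2cm": (16, 25), "2-4cm": (51, 59), ">4cm": (25, 25)},
    "combined": {"<2cm": (16, 25), "2-4cm": (54, 59), ">4cm": (25, 25)},
}
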