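#!/usr/bin/env python
"""Run the cohort statistics on the simulated study: Spearman correlations of
the asymmetry ratios with walking-ability measures, the coarse classification
tree (with five-fold cross-validation and resubstitution confusion), the
FMA-LE threshold comparator, and the post-hoc ANOVA across classification
subgroups.  Writes results/correlations.csv, results/tree.json and
results/classification_report.md."""

import json
from pathlib import Path

import pandas as pd

from modwalk import cohort, synth
from modwalk.cohort import MULTI, TWO

SEED = 20260921
OUT = Path("results")

MEASURES = [
    ("fma_le", "FMA-LE"),
    ("dgi", "DGI"),
    ("smwt_m", "SMWT"),
    ("bbs", "BBS"),
    ("ss_speed_m_s", "self-selected speed"),
    ("pp_deviation", "Pp deviation"),
    ("psr_deviation", "PSR deviation"),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    subjects = synth.generate_cohort(43, 0, "reference", seed=SEED)
    table = cohort.subject_table(subjects)

    rows = []
    for tract in ("asymm_cst", "asymm_crp"):
        for col, label in MEASURES:
            r = cohort.spearman(table[tract], table[col], tract, label)
            rows.append(
                {
                    "predictor": tract,
                    "measure": label,
                    "rho": round(r.rho, 3),
                    "p": round(r.p_value, 4),
                    "df": r.df,
                }
            )
    corr = pd.DataFrame(rows)
    corr.to_csv(OUT / "correlations.csv", index=False)
    print("correlations (seed {}):".format(SEED))
    print(corr.to_string(index=False))

    X = table[["asymm_cst", "asymm_crp"]].to_numpy()
    y = table["pattern_class"].to_numpy()
    cv = cohort.cross_validate(X, y, k_folds=5, seed=SEED)
    resub = cv.resubstitution_confusion
    disp = cohort.ConfusionSummary.display

    fma_pred = [cohort.fma_threshold_classifier(v) for v in table.fma_le_synergy]
    fma_conf = cohort.confusion_report(y, fma_pred)

    (OUT / "tree.json").write_text(
        json.dumps({"rules": cv.model.to_rules(), "n_splits": cv.model.n_splits},
                   indent=2) + "\n"
    )

    report = [
        "# Classification report (simulated cohort)",
        "",
        f"Coarse tree on (CST, CRP) asymmetry, seed {SEED}:",
        "",
        *[f"- {r}" for r in cv.model.to_rules()],
        "",
        f"- resubstitution: {disp(resub.per_class_percent(MULTI))}% of "
        f"more-than-two and {disp(resub.per_class_percent(TWO))}% of "
        f"two-module subjects correct; overall "
        f"{disp(resub.overall_percent)}%",
        f"- five-fold cross-validated accuracy: {disp(cv.accuracy_percent)}%",
        f"- FMA-LE < 15 comparator: overall {disp(fma_conf.overall_percent)}%, "
        f"false-positive two-module rate "
        f"{disp(fma_conf.false_positive_two_percent)}%",
        "",
    ]

    sub = table.dropna(subset=["subgroup"])
    groups = {
        sg: sub.loc[sub.subgroup == sg, "fma_le"].to_numpy()
        for sg in ("multi", "moderate_two", "severe_two")
    }
    f, p, pairwise = cohort.anova_posthoc(groups)
    report += [
        f"Post-hoc one-way ANOVA on FMA-LE across subgroups: F={f:.2f}, p={p:.4g}",
        *[
            f"- {a} vs {b}: Bonferroni p = {pv:.3g}"
            for (a, b), pv in pairwise.items()
        ],
        "",
    ]
    (OUT / "classification_report.md").write_text("\n".join(report))
    print("\n".join(report))
    print(f"wrote {OUT}/correlations.csv, tree.json, classification_report.md")


if __name__ == "__main__":
    main()
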