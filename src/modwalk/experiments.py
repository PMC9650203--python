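"""End-to-end evaluation experiments.

Each function runs one self-contained experiment on synthetic data through
the full pipeline and returns plain numbers (rates, errors, percentages).
They are shared by the acceptance tests and by ``scripts/acceptance.py`` so
that both always measure the same computation.
"""

from __future__ import annotations

import numpy as np

from . import cohort as cohort_mod
from . import emg as emg_mod
from . import gaitmetrics, modules, synth
from .cohort import MULTI, TWO


def _derive_seed(rng_key: list[int]) -> int:
    return int(np.random.default_rng(rng_key).integers(0, 2**31 - 1))


# --- module-count recovery -------------------------------------------------


def analyze_subject_modules(
    config: synth.SyntheticSubjectConfig,
    truth: synth.GroundTruthModules,
    restarts: int = 5,
) -> tuple[modules.ModuleCountDecision, float]:
    """Full EMG pipeline for one synthetic subject: raw EMG -> envelope ->
    averaged normalized cycle -> bins -> module-count selection.  Returns the
    decision and the mean matched-module cosine similarity of the fit at the
    true module count."""
    rec, events = synth.generate_emg(config, truth)
    env = emg_mod.envelope(rec)
    cyc = emg_mod.segment_and_normalize(env, events)
    bins = emg_mod.bin_average(cyc, events)
    norm = emg_mod.normalize_amplitude(cyc, bins)
    fit_seed = config.seed % 100_000
    decision = modules.select_module_number(
        norm.matrix, bins.bin_edges_pct, seed=fit_seed, restarts=restarts
    )
    fit = None
    for k, _, dec in decision.trail:
        if k == truth.n_modules:
            fit = dec
    if fit is None:
        fit = modules.nnmf_fit(
            norm.matrix, truth.n_modules, seed=fit_seed, restarts=restarts
        )
    _, sims = modules.match_modules(fit.W, truth.weights)
    return decision, float(np.mean(sims))


def module_recovery_experiment(
    n_per_k: int = 100,
    true_ks: tuple[int, ...] = (2, 3, 4),
    noise_sd: float = 0.05,
    seed: int = 1,
    restarts: int = 5,
) -> dict:
    """Module-count recovery rate and matched-module similarity over seeded
    synthetic subjects at the study's envelope noise level."""
    correct = 0
    sims = []
    per_k = {}
    for k in true_ks:
        k_correct = 0
        for i in range(n_per_k):
            sub_seed = _derive_seed([seed, k, i])
            config = synth.SyntheticSubjectConfig(
                true_n_modules=k, noise_sd=noise_sd, seed=sub_seed
            )
            truth = synth.make_truth_templates(k, sub_seed)
            decision, sim = analyze_subject_modules(config, truth, restarts)
            k_correct += decision.k_selected == k
            sims.append(sim)
        per_k[k] = 100.0 * k_correct / n_per_k
        correct += k_correct
    n = n_per_k * len(true_ks)
    return {
        "recovery_rate_pct": 100.0 * correct / n,
        "recovery_rate_per_k_pct": per_k,
        "mean_cosine_similarity": float(np.mean(sims)),
        "n_subjects": n,
    }


# --- VAF oracle equivalence ------------------------------------------------


def vaf_bruteforce(X: np.ndarray, R: np.ndarray, rows, cols) -> float:
    """Independent uncentered VAF: 100 * (1 - sum(e^2)/sum(x^2)) over an
    arbitrary row/column partition (test oracle)."""
    x = X[np.ix_(rows, cols)]
    e = x - R[np.ix_(rows, cols)]
    return 100.0 * (1.0 - float((e**2).sum()) / float((x**2).sum()))


def vaf_equivalence_experiment(n_partitions: int = 1000, seed: int = 1) -> dict:
    """Compare compute_vaf against the brute-force formula on random data,
    random valid decompositions and random bin partitions; also check the
    closed-form half-amplitude case (reconstruction = X/2 -> VAF = 75%)."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    checked = 0
    while checked < n_partitions:
        m = int(rng.integers(2, 9))
        X = rng.random((m, 101)) + 0.05
        k = int(rng.integers(1, m + 1))
        W = rng.random((m, k))
        C = rng.random((k, 101))
        dec = modules.ModuleDecomposition(W, C, k, 0.0, 0, 0)
        n_bins = int(rng.integers(2, 7))
        inner = np.sort(rng.choice(np.arange(1, 100), n_bins - 1, replace=False))
        edges = np.concatenate(([0.0], inner.astype(float), [100.0]))
        rep = modules.compute_vaf(X, dec, edges)
        R = dec.reconstruction
        rows_all = np.arange(m)
        cols_all = np.arange(101)
        diffs = [abs(rep.vaf_overall - vaf_bruteforce(X, R, rows_all, cols_all))]
        for i in range(m):
            diffs.append(
                abs(rep.vaf_per_muscle[i] - vaf_bruteforce(X, R, [i], cols_all))
            )
            checked += 1
        for j, colsel in enumerate(modules._bin_column_slices(edges)):
            diffs.append(abs(rep.vaf_per_bin[j] - vaf_bruteforce(X, R, rows_all, colsel)))
            checked += 1
        max_diff = max(max_diff, max(diffs))

    X = rng.random((8, 101)) + 0.1
    dec_half = modules.ModuleDecomposition(
        np.eye(8) * 0.5, X.copy(), 8, 0.0, 0, 0
    )
    rep_half = modules.compute_vaf(X, dec_half)
    half_vals = [rep_half.vaf_overall, *rep_half.vaf_per_muscle]
    return {
        "max_abs_diff": float(max_diff),
        "half_reconstruction_vaf_pct": float(rep_half.vaf_overall),
        "half_reconstruction_max_err": float(
            np.max(np.abs(np.array(half_vals) - 75.0))
        ),
        "n_partitions": checked,
    }


# --- propulsion recovery ---------------------------------------------------


def pp_recovery_experiment(
    pp_targets: tuple[float, ...] = (0.3, 0.4, 0.5), seed: int = 1
) -> dict:
    """Estimate Pp on generated GRF for each target and report the largest
    absolute error; PSR recovery is checked at machine precision."""
    max_err = 0.0
    max_psr_err = 0.0
    for i, pp in enumerate(pp_targets):
        cfg = synth.SyntheticSubjectConfig(
            pp_true=pp, psr_true=0.45, seed=_derive_seed([seed, i])
        )
        trace, steps, _ = synth.generate_grf(cfg)
        est = gaitmetrics.paretic_propulsion(trace)
        max_err = max(max_err, abs(est - pp))
        max_psr_err = max(
            max_psr_err, abs(gaitmetrics.paretic_step_ratio(steps) - 0.45)
        )
    return {
        "max_abs_pp_error": float(max_err),
        "max_abs_psr_error": float(max_psr_err),
        "n_targets": len(pp_targets),
    }


# --- statistics oracle equivalence -----------------------------------------


def spearman_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average ranks (test oracle)."""

    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size)
        sv = v[order]
        i = 0
        while i < v.size:
            j = i
            while j < v.size and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2.0 + 1.0
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def mwu_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive pair count U = #{a_i > b_j} + 0.5 #ties (test oracle)."""
    u = 0.0
    for ai in a:
        for bj in b:
            u += 1.0 if ai > bj else (0.5 if ai == bj else 0.0)
    return u


def anova_f_bruteforce(samples: list[np.ndarray]) -> float:
    """Between/within mean-squares ratio from first principles (test oracle)."""
    allv = np.concatenate(samples)
    grand = allv.mean()
    ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(float(((s - s.mean()) ** 2).sum()) for s in samples)
    df_b = len(samples) - 1
    df_w = allv.size - len(samples)
    return float((ss_between / df_b) / (ss_within / df_w))


def stats_equivalence_experiment(n_sets: int = 200, seed: int = 1) -> dict:
    """Max absolute deviation of the pipeline's Spearman rho, Mann-Whitney U
    and ANOVA F from exhaustive brute-force computations on random small
    samples (with ties)."""
    rng = np.random.default_rng(seed)
    d_rho = d_u = d_f = 0.0
    for _ in range(n_sets):
        n = int(rng.integers(5, 21))
        x = rng.integers(0, 12, n).astype(float)  # integer-valued: ties likely
        y = (x + rng.integers(-4, 5, n)).astype(float)
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            res = cohort_mod.spearman(x, y)
            d_rho = max(d_rho, abs(res.rho - spearman_bruteforce(x, y)))

        a = rng.integers(0, 10, int(rng.integers(3, 12))).astype(float)
        b = rng.integers(0, 10, int(rng.integers(3, 12))).astype(float)
        u, _ = cohort_mod.mann_whitney(a, b)
        d_u = max(d_u, abs(u - mwu_bruteforce(a, b)))

        n_groups = int(rng.integers(2, 5))
        samples = [rng.random(int(rng.integers(3, 9))) for _ in range(n_groups)]
        f, _, _ = cohort_mod.anova_posthoc(
            {f"g{i}": s for i, s in enumerate(samples)}
        )
        d_f = max(d_f, abs(f - anova_f_bruteforce(samples)))
    return {
        "spearman_max_abs_diff": float(d_rho),
        "mannwhitney_max_abs_diff": float(d_u),
        "anova_max_abs_diff": float(d_f),
        "n_sets": n_sets,
    }


# --- classification tree behavior ------------------------------------------


def separable_split_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Midpoint of the closest cross-class pair of a 1-D separable sample
    (exhaustive threshold search oracle)."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    change = np.flatnonzero(ys[1:] != ys[:-1])
    assert change.size == 1, "data must change class exactly once when sorted"
    i = change[0]
    return float((xs[i] + xs[i + 1]) / 2.0)


def tree_split_experiment(n_sets: int = 50, seed: int = 1) -> dict:
    """On random 1-D perfectly separable data, the fitted root split must
    equal the midpoint oracle."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_sets):
        n = int(rng.integers(6, 30))
        x = np.sort(rng.normal(size=n))
        cut = int(rng.integers(1, n))
        y = np.array([TWO] * cut + [MULTI] * (n - cut))
        perm = rng.permutation(n)
        model = cohort_mod.fit_coarse_tree(
            x[perm, None], y[perm], feature_names=("x",)
        )
        max_diff = max(max_diff, abs(model.root.threshold - separable_split_oracle(x, y)))
    return {"max_abs_split_diff": float(max_diff), "n_sets": n_sets}


def printed_rule_probe_experiment() -> dict:
    """Probe the fixture tree carrying the published cutoffs (CRP < 0.27 or
    CST < -0.02 -> two modules) on points inside, outside and on the
    boundaries of the two cut regions."""
    model = cohort_mod.printed_rule_tree()
    probes = [
        ((0.50, 0.20), TWO),  # low CRP asymmetry
        ((-0.10, 0.50), TWO),  # negative CST asymmetry
        ((0.50, 0.50), MULTI),  # neither rule fires
        ((-0.02, 0.27), MULTI),  # both exactly at cutoff: strict less-than
        ((0.0, 0.269), TWO),
        ((-0.021, 0.271), TWO),
        ((0.5, 0.271), MULTI),
    ]
    hits = sum(
        cohort_mod.predict_tree(model, (cst, crp)) == want
        for (cst, crp), want in probes
    )
    return {"agreement_pct": 100.0 * hits / len(probes), "n_probes": len(probes)}


def tree_root_experiment(
    n_cohorts: int = 50, n_stroke: int = 43, seed: int = 1
) -> dict:
    """Fraction of seeded reference cohorts whose fitted tree splits first
    on CRP asymmetry (the published tree's primary split)."""
    crp_roots = 0
    for c in range(n_cohorts):
        subjects = synth.generate_cohort(
            n_stroke, 0, "reference", seed=_derive_seed([seed, c])
        )
        table = cohort_mod.subject_table(subjects)
        X = table[["asymm_cst", "asymm_crp"]].to_numpy()
        y = table["pattern_class"].to_numpy()
        model = cohort_mod.fit_coarse_tree(X, y)
        crp_roots += model.root.feature == 1
    return {
        "crp_root_pct": 100.0 * crp_roots / n_cohorts,
        "n_cohorts": n_cohorts,
    }


# --- correlation direction recovery ----------------------------------------

#: Significant correlation directions between the asymmetry ratios and the
#: walking-ability measures (sign of the expected Spearman rho).
SIGN_PATTERN = (
    ("asymm_cst", "fma_le", +1),
    ("asymm_cst", "pp_deviation", -1),
    ("asymm_crp", "fma_le", +1),
    ("asymm_crp", "dgi", +1),
    ("asymm_crp", "smwt_m", +1),
    ("asymm_crp", "bbs", +1),
    ("asymm_crp", "ss_speed_m_s", +1),
    ("asymm_crp", "pp_deviation", -1),
)


def direction_recovery_experiment(
    n_cohorts: int = 100, n_stroke: int = 43, seed: int = 1
) -> dict:
    """Fraction of seeded reference cohorts whose Spearman correlations all
    carry the configured signs."""
    all_match = 0
    for c in range(n_cohorts):
        subjects = synth.generate_cohort(
            n_stroke, 0, "reference", seed=_derive_seed([seed, 17, c])
        )
        table = cohort_mod.subject_table(subjects)
        ok = True
        for x, y, sign in SIGN_PATTERN:
            rho = cohort_mod.spearman(table[x], table[y], x, y).rho
            if np.sign(rho) != sign:
                ok = False
                break
        all_match += ok
    return {
        "sign_recovery_pct": 100.0 * all_match / n_cohorts,
        "n_cohorts": n_cohorts,
    }


# --- printed confusion arithmetic ------------------------------------------


def _labels_from_counts(cells: list[tuple[str, str, int]]) -> tuple[list, list]:
    true_labels: list = []
    pred_labels: list = []
    for t, p, n in cells:
        true_labels += [t] * n
        pred_labels += [p] * n
    return true_labels, pred_labels


def printed_confusion_experiment() -> dict:
    """Reproduce the published classification percentages from their integer
    counts: the streamline-asymmetry tree correctly classified 28 of 30
    more-than-two-module and 7 of 13 two-module subjects; the FMA-LE < 15
    comparator 24 of 30 and 10 of 13."""
    tree = cohort_mod.confusion_report(
        *_labels_from_counts(
            [
                (MULTI, MULTI, 28),
                (MULTI, TWO, 2),
                (TWO, TWO, 7),
                (TWO, MULTI, 6),
            ]
        )
    )
    fma = cohort_mod.confusion_report(
        *_labels_from_counts(
            [
                (MULTI, MULTI, 24),
                (MULTI, TWO, 6),
                (TWO, TWO, 10),
                (TWO, MULTI, 3),
            ]
        )
    )
    disp = cohort_mod.ConfusionSummary.display
    return {
        "tree_multi_correct_pct": disp(tree.per_class_percent(MULTI)),
        "tree_two_correct_pct": disp(tree.per_class_percent(TWO)),
        "tree_overall_pct": disp(tree.overall_percent),
        "tree_false_positive_two_pct": disp(tree.false_positive_two_percent),
        "fma_multi_correct_pct": disp(fma.per_class_percent(MULTI)),
        "fma_two_correct_pct": disp(fma.per_class_percent(TWO)),
        "fma_overall_pct": disp(fma.overall_percent),
        "n_subjects": tree.n,
    }
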