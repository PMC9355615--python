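"""Self-contained acceptance checks exercised by the test suite and the
reporting script.

Each criterion function recomputes its quantities from scratch — generating
inputs, running the package, and measuring the outcome — and returns a plain
metrics dict. Seeds control every source of randomness.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .distances import bray_curtis
from .guild_partition import classify_otu, partition_table
from .matrix_stats import (forward_select_mrm, mantel, mrm, partial_mantel,
                           permanova, variation_partitioning)
from .null_model import beta_deviation, mean_deviation_test
from .preprocess import community_weighted_mean, rarefy
from .synthetic_data import (AssemblyScenario, assemble_communities,
                             simulate_guild_annotation, simulate_pool)
from .tabular_io import (DistanceMatrix, OtuTable, read_distance_matrix,
                         read_otu_table, write_distance_matrix,
                         write_otu_table)

__all__ = ["null_self_consistency", "regime_discrimination",
           "oracle_equivalence", "driver_recovery", "deterministic_plumbing"]

_N_DATASETS = 20
_N_SITES = 10
_READS = 2000
_N_NULL = 499
_N_OTUS = 200


def _neutral_like_scenario(regime: str, seed: int, **kw) -> AssemblyScenario:
    params = dict(n_sites=_N_SITES, quadrats_per_site=1, depths=("surface",),
                  reads_per_sample=_READS, seed=seed)
    params.update(kw)
    return AssemblyScenario(regime=regime, **params)


def _dataset_deviation(regime: str, seed: int, **kw) -> dict:
    ss = np.random.SeedSequence(seed)
    s_pool, s_asm, s_null = (int(c.generate_state(1)[0]) for c in ss.spawn(3))
    pool = simulate_pool(_N_OTUS, 1.5, seed=s_pool)
    ds = assemble_communities(pool,
                              _neutral_like_scenario(regime, s_asm, **kw))
    result = beta_deviation(ds.otu_table, n_null=_N_NULL, seed=s_null)
    return mean_deviation_test(result)


def null_self_consistency(seed: int) -> dict:
    """Criterion 1: neutral-process data yields centred, non-significant
    mean ses deviations."""
    tests = [_dataset_deviation("neutral", seed + k)
             for k in range(_N_DATASETS)]
    means = np.array([t["mean"] for t in tests])
    pvals = np.array([t["p"] for t in tests])
    return {
        "n_datasets": _N_DATASETS,
        "n_pairs_per_dataset": tests[0]["n_pairs"],
        "grand_mean_ses": float(means.mean()),
        "nonsignificant_at_0.01": int((pvals >= 0.01).sum()),
        "per_dataset_means": means.tolist(),
        "per_dataset_p": pvals.tolist(),
    }


def regime_discrimination(seed: int) -> dict:
    """Criterion 2: heterogeneous selection positive, homogeneous negative."""
    het = [_dataset_deviation("heterogeneous_selection", seed + 1000 + k,
                              niche_breadth=8.0)
           for k in range(_N_DATASETS)]
    hom = [_dataset_deviation("homogeneous_selection", seed + 2000 + k,
                              niche_breadth=8.0)
           for k in range(_N_DATASETS)]
    het_hits = sum(t["mean"] > 0 and t["p"] < 0.01 for t in het)
    hom_hits = sum(t["mean"] < 0 and t["p"] < 0.01 for t in hom)
    return {
        "n_datasets": _N_DATASETS,
        "heterogeneous_positive_significant": int(het_hits),
        "homogeneous_negative_significant": int(hom_hits),
        "heterogeneous_mean_of_means": float(np.mean([t["mean"]
                                                      for t in het])),
        "homogeneous_mean_of_means": float(np.mean([t["mean"]
                                                    for t in hom])),
    }


# --- criterion 3: brute-force enumeration oracles (independent code paths) --


def _line_matrix(rng, n, labels=None):
    pts = rng.uniform(0, 10, n)
    vals = np.abs(pts[:, None] - pts[None, :])
    return DistanceMatrix(tuple(labels or (f"s{i}" for i in range(n))), vals)


def _oracle_mantel(dx, dy):
    n = dx.n
    iu = np.triu_indices(n, k=1)
    y = dy.values[iu]
    r_obs = np.corrcoef(dx.values[iu], y)[0, 1]
    count = sum(
        abs(np.corrcoef(dx.values[np.ix_(p, p)][iu], y)[0, 1]) >= abs(r_obs)
        for p in itertools.permutations(range(n)))
    return count / math.factorial(n)


def _oracle_partial(dx, dy, dz):
    n = dx.n
    iu = np.triu_indices(n, k=1)
    y, z = dy.values[iu], dz.values[iu]
    Z = np.column_stack([np.ones_like(z), z])

    def resid(v):
        return v - Z @ np.linalg.lstsq(Z, v, rcond=None)[0]

    ry = resid(y)

    def pr(xv):
        return np.corrcoef(resid(xv), ry)[0, 1]

    obs = pr(dx.values[iu])
    count = sum(abs(pr(dx.values[np.ix_(p, p)][iu])) >= abs(obs)
                for p in itertools.permutations(range(n)))
    return obs, count / math.factorial(n)


def _oracle_mrm_p(dy, predictors):
    n = dy.n
    iu = np.triu_indices(n, k=1)
    m = len(iu[0])

    def zsc(v):
        return (v - v.mean()) / v.std(ddof=1)

    X = np.column_stack([np.ones(m)]
                        + [zsc(p.values[iu]) for p in predictors.values()])
    k = X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)

    def tvals(yv):
        yv = zsc(yv)
        beta = np.linalg.lstsq(X, yv, rcond=None)[0]
        rss = float((yv - X @ beta) @ (yv - X @ beta))
        se = np.sqrt(np.diagonal(xtx_inv) * rss / (m - k))
        return beta[1:] / se[1:]

    t_obs = tvals(dy.values[iu])
    counts = np.zeros(len(predictors))
    for p in itertools.permutations(range(n)):
        counts += np.abs(tvals(dy.values[np.ix_(p, p)][iu])) \
            >= np.abs(t_obs) - 1e-12
    return counts / math.factorial(n)


def _oracle_permanova_p(d, groups):
    n = d.n
    d2 = d.values ** 2
    uniq = sorted(set(groups))

    def f_stat(g):
        ss_t = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ss_w = 0.0
        for label in uniq:
            members = [i for i, gi in enumerate(g) if gi == label]
            ss_w += sum(d2[i, j] for i in members for j in members
                        if i < j) / len(members)
        return ((ss_t - ss_w) / (len(uniq) - 1)) / (ss_w / (n - len(uniq)))

    f_obs = f_stat(groups)
    garr = np.array(groups)
    count = sum(f_stat(garr[list(p)]) >= f_obs - 1e-12
                for p in itertools.permutations(range(n)))
    return count / math.factorial(n)


def oracle_equivalence(seed: int) -> dict:
    """Criterion 3: exact-mode p-values equal exhaustive enumeration."""
    rng = np.random.default_rng(seed)
    checks = 0
    matches = 0
    partial_r_err = 0.0
    for _ in range(3):
        dx, dy, dz = (_line_matrix(rng, 5) for _ in range(3))
        res = mantel(dx, dy, method="exact")
        matches += res.p == _oracle_mantel(dx, dy)
        checks += 1
        pres = partial_mantel(dx, dy, dz, method="exact")
        r_oracle, p_oracle = _oracle_partial(dx, dy, dz)
        partial_r_err = max(partial_r_err, abs(pres.r - r_oracle))
        matches += (pres.p == p_oracle) and abs(pres.r - r_oracle) <= 1e-12
        checks += 1
        preds = {"a": _line_matrix(rng, 5, dx.labels),
                 "b": _line_matrix(rng, 5, dx.labels)}
        mres = mrm(dy, preds, method="exact")
        oracle_p = _oracle_mrm_p(dy, preds)
        matches += (mres.p_per_predictor["a"] == oracle_p[0]
                    and mres.p_per_predictor["b"] == oracle_p[1])
        checks += 1
        d6 = _line_matrix(rng, 6)
        groups = ["g1"] * 3 + ["g2"] * 3
        perm = permanova(d6, groups, method="exact")
        matches += perm.p == _oracle_permanova_p(d6, groups)
        checks += 1
    return {"n_checks": checks, "n_matching": int(matches),
            "max_partial_r_error": float(partial_r_err)}


def driver_recovery(seed: int, n_runs: int = 50) -> dict:
    """Criterion 4: forward MRM finds the constructed driver; VPA recovers
    constructed variance shares."""
    rng = np.random.default_rng(seed)
    n = 12
    labels = tuple(f"s{i}" for i in range(n))
    m = n * (n - 1) // 2
    srl_hits = 0
    for _ in range(n_runs):
        z_srl = rng.normal(size=m)
        y = 0.8 * z_srl + 0.6 * rng.normal(size=m)
        candidates = {"D_SRL": DistanceMatrix.from_condensed(labels, z_srl,
                                                             signed=True)}
        for i in range(4):
            candidates[f"noise{i}"] = DistanceMatrix.from_condensed(
                labels, rng.normal(size=m), signed=True)
        dy = DistanceMatrix.from_condensed(labels, y, signed=True)
        res = forward_select_mrm(dy, candidates, alpha=0.05, n_perm=199,
                                 seed=int(rng.integers(2 ** 31)))
        srl_hits += ("D_SRL" in res.selected
                     and res.p_per_predictor["D_SRL"] < 0.05)
    # VPA: centred orthonormal construction with known variance shares
    a2, b2 = 0.5, 0.3
    env_err, sp_err = [], []
    for _ in range(n_runs):
        raw = rng.normal(size=(m, 3))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        y = (np.sqrt(a2) * q[:, 0] + np.sqrt(b2) * q[:, 1]
             + np.sqrt(1 - a2 - b2) * q[:, 2])
        res = variation_partitioning(
            DistanceMatrix.from_condensed(labels, y, signed=True),
            env={"e": DistanceMatrix.from_condensed(labels, q[:, 0],
                                                    signed=True)},
            space={"s": DistanceMatrix.from_condensed(labels, q[:, 1],
                                                      signed=True)})
        env_err.append(res.pure_env - a2)
        sp_err.append(res.pure_space - b2)
    return {
        "n_runs": n_runs,
        "srl_selected_significant": int(srl_hits),
        "vpa_pure_env_mean_error": float(np.mean(env_err)),
        "vpa_pure_space_mean_error": float(np.mean(sp_err)),
        "vpa_pure_env_max_abs_error": float(np.max(np.abs(env_err))),
        "vpa_pure_space_max_abs_error": float(np.max(np.abs(sp_err))),
    }


def deterministic_plumbing(seed: int, tmp_dir) -> dict:
    """Criterion 5: exact rarefaction, byte-identical round trips and
    pipeline reruns, partition truth recovery, CWM dot products."""
    from pathlib import Path

    import yaml

    from .pipeline import run_pipeline
    from .tabular_io import load_config

    tmp = Path(tmp_dir)
    tmp.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    checks: dict[str, bool] = {}

    # rarefaction row sums exact
    counts = rng.integers(0, 60, size=(6, 15))
    counts[:, 0] += 30
    table = OtuTable(tuple(f"s{i}" for i in range(6)),
                     tuple(f"o{j}" for j in range(15)), counts)
    rare = rarefy(table, 25, seed=seed)
    checks["rarefaction_row_sums_exact"] = bool((rare.row_sums() == 25).all())

    # OTU table round trip byte-identical
    p1, p2 = tmp / "t1.tsv", tmp / "t2.tsv"
    write_otu_table(table, p1)
    write_otu_table(read_otu_table(p1), p2)
    checks["otu_roundtrip_byte_identical"] = p1.read_bytes() == p2.read_bytes()

    # distance matrix round trip byte-identical
    d = bray_curtis(table)
    q1, q2 = tmp / "d1.tsv", tmp / "d2.tsv"
    write_distance_matrix(d, q1)
    write_distance_matrix(read_distance_matrix(q1), q2)
    checks["distance_roundtrip_byte_identical"] = (q1.read_bytes()
                                                  == q2.read_bytes())

    # guild partition recovers generator truth exactly
    pool = simulate_pool(300, 1.5, seed=seed + 1)
    ann = simulate_guild_annotation(pool, seed=seed + 2)
    full = OtuTable(("a", "b"), pool.otu_ids,
                    rng.integers(0, 10, size=(2, 300)))
    parts = partition_table(full, ann)
    truth: dict[str, set] = {"mycorrhizal": set(), "saprotrophic": set(),
                             "pathotrophic": set()}
    for record in ann:
        cls = classify_otu(record)
        if cls in truth:
            truth[cls].add(record.otu_id)
    checks["partition_matches_truth"] = all(
        set(parts[g].otu_ids) == members for g, members in truth.items())

    # CWM equals the hand-computed dot product
    p = rng.dirichlet(np.ones(6))
    tvals = rng.uniform(1, 40, 6)
    species = [f"sp{i}" for i in range(6)]
    community = pd.DataFrame([p], index=["Q1"], columns=species)
    traits = pd.DataFrame(
        {"SRL": tvals},
        index=pd.MultiIndex.from_product([["Q1"], species],
                                         names=["quadrat_id", "species"]))
    cwm = community_weighted_mean(community, traits, "SRL")["Q1"]
    checks["cwm_matches_dot_product"] = abs(cwm - float(p @ tvals)) < 1e-12

    # fixed-seed pipeline rerun byte-identical
    cfg_path = tmp / "config.yml"
    cfg_path.write_text(yaml.safe_dump({
        "simulate": {"regime": "neutral", "n_sites": 6,
                     "quadrats_per_site": 1, "depths": ["surface"],
                     "reads_per_sample": 400, "n_otus": 80},
        "n_null": 49, "n_perm": 99, "seed": seed,
        "guilds": ["total"],
    }))
    config = load_config(cfg_path)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        run_pipeline(config, out_dir=tmp / "r1")
        run_pipeline(config, out_dir=tmp / "r2")
    files = sorted(p.relative_to(tmp / "r1")
                   for p in (tmp / "r1").rglob("*") if p.is_file())
    checks["pipeline_rerun_byte_identical"] = bool(files) and all(
        (tmp / "r1" / f).read_bytes() == (tmp / "r2" / f).read_bytes()
        for f in files)

    return {"checks": checks,
            "n_checks": len(checks),
            "n_passed": int(sum(checks.values()))}
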