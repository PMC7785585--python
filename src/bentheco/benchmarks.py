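"""Self-calibration and ground-truth recovery benchmarks.

These routines exercise the pipeline against data with known structure:
null-process self-calibration for betaNTI and RCbray, regime recovery of
the assembly partition on simulated surveys, and SparCC recovery of planted
basis correlations.  They back both the validation test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from ._util import derive_seed
from .assembly import PROCESS_LABELS, bnti, classify_pair, raup_crick_bray
from .data_model import OtuTable
from .network import sparcc
from .synthetic import (
    ScenarioConfig,
    scenario_presets,
    simulate_compositional,
    simulate_scenario,
    simulate_tree,
)

__all__ = [
    "bnti_null_calibration",
    "rc_null_calibration",
    "rc_identical_pairs",
    "scenario_partition",
    "sparcc_recovery",
]


def bnti_null_calibration(
    seed: int,
    n_tables: int = 16,
    n_samples: int = 8,
    n_otus: int = 100,
    depth: int = 1000,
    n_null: int = 999,
) -> tuple[float, int]:
    """Coverage of betaNTI in [-2, 2] on communities from the null process.

    Communities are assembled with no phylogenetic structure (independent
    lognormal profiles, random tree), i.e. the OTU-tip assignment is itself
    random, so betaNTI should be approximately standard normal.  Returns
    (coverage, n_pairs) pooled over replicate tables.
    """
    rng = np.random.default_rng(seed)
    values = []
    for rep in range(n_tables):
        tree = simulate_tree(n_otus, derive_seed(seed, f"cal_tree_{rep}"))
        otus = [t.name for t in tree.tips()]
        counts = np.vstack([
            rng.multinomial(depth, (lambda w: w / w.sum())(rng.lognormal(0, 1, n_otus)))
            for _ in range(n_samples)
        ])
        table = OtuTable([f"s{i}" for i in range(n_samples)], otus, counts)
        z = bnti(table, tree, n_null=n_null, seed=derive_seed(seed, f"cal_null_{rep}"))
        values.append(z.condensed())
    v = np.concatenate(values)
    v = v[~np.isnan(v)]
    coverage = float(np.mean((v >= -2) & (v <= 2)))
    return coverage, int(v.size)


def rc_null_calibration(
    seed: int,
    n_pairs: int = 210,
    n_otus: int = 100,
    depth: int = 1000,
    n_null: int = 999,
) -> tuple[float, int]:
    """Mean RCbray over independent sample pairs drawn from the RC null itself.

    A reference drift table fixes the regional pool (occurrence frequencies
    and regional abundances); independent pairs of samples are then drawn by
    the same richness- and abundance-preserving procedure the RC null uses,
    and each pair is scored against that same pool.  Pairs are generated
    independently so the mean's sampling error shrinks as 1/sqrt(n_pairs);
    the mean should sit near 0.  Returns (mean RC, n_pairs).
    """
    rng = np.random.default_rng(seed)
    pool = rng.lognormal(0, 1, n_otus)
    base = np.vstack([rng.multinomial(depth, pool / pool.sum())
                      for _ in range(21)])
    occupancy = (base > 0).sum(axis=0).astype(float)
    regional = base.sum(axis=0).astype(float)
    p_occ = occupancy / occupancy.sum()
    richness_pool = (base > 0).sum(axis=1)

    def draw_sample() -> np.ndarray:
        richness = int(rng.choice(richness_pool))
        row = np.zeros(n_otus, dtype=np.int64)
        chosen = rng.choice(n_otus, size=richness, replace=False, p=p_occ)
        row[chosen] = 1
        pr = regional[chosen] / regional[chosen].sum()
        row[chosen] += rng.multinomial(depth - richness, pr)
        return row

    values = []
    for k in range(n_pairs):
        table = OtuTable(["a", "b"], [f"o{j}" for j in range(n_otus)],
                         np.vstack([draw_sample(), draw_sample()]))
        rc = raup_crick_bray(table, n_null=n_null,
                             seed=derive_seed(seed, f"rc_cal_{k}"),
                             occupancy_weights=occupancy,
                             regional_abundance=regional)
        values.append(rc["a", "b"])
    return float(np.mean(values)), len(values)


def rc_identical_pairs(seed: int, n_otus: int = 30, depth: int = 500,
                       n_null: int = 999) -> float:
    """Maximum RCbray over duplicated-sample pairs (expected near -1)."""
    rng = np.random.default_rng(seed)
    prof = rng.lognormal(0, 1, n_otus)
    a = rng.multinomial(depth, prof / prof.sum())
    b = rng.multinomial(depth, prof / prof.sum())
    table = OtuTable(["a1", "a2", "b1", "b2"], [f"o{j}" for j in range(n_otus)],
                     np.vstack([a, a, b, b]))
    rc = raup_crick_bray(table, n_null=n_null, seed=derive_seed(seed, "rc_ident"))
    return float(max(rc["a1", "a2"], rc["b1", "b2"]))


def scenario_partition(
    regime: str,
    seed: int,
    n_replicates: int = 3,
    n_null: int = 999,
) -> dict[str, float]:
    """Pooled assembly-process fractions for one named regime preset.

    Runs ``n_replicates`` independent surveys (fresh tree, traits, and
    communities each) at the preset's full design (9 sites x 4 layers,
    300 OTUs, depth 10,000) and pools all sample pairs before computing the
    fractions; pooling averages out tree-realization variance in the
    phylogenetic signal.
    """
    presets = scenario_presets()
    if regime not in presets:
        raise ValueError(f"unknown regime {regime!r}; options: {sorted(presets)}")
    z_all, rc_all = [], []
    for rep in range(n_replicates):
        cfg = ScenarioConfig(seed=derive_seed(seed, f"{regime}_rep{rep}"),
                             **presets[regime])
        data = simulate_scenario(cfg)
        z = bnti(data.table, data.tree, n_null=n_null,
                 seed=derive_seed(seed, f"{regime}_bnti_{rep}"))
        rc = raup_crick_bray(data.table, n_null=n_null,
                             seed=derive_seed(seed, f"{regime}_rc_{rep}"))
        z_all.append(z.condensed())
        rc_all.append(rc.condensed())
    z = np.concatenate(z_all)
    rc = np.concatenate(rc_all)
    labels = np.asarray([
        classify_pair(zi, ri) for zi, ri in zip(z, rc) if not np.isnan(zi)
    ])
    return {lab: float(np.mean(labels == lab)) for lab in PROCESS_LABELS}


def sparcc_recovery(seed: int, d: int = 10) -> dict[str, float]:
    """Planted-correlation and compositional-bias checks for SparCC.

    The planted check estimates a 0.8 basis correlation from 200 samples at
    depth 10,000.  The identity check uses 2,000 samples so that sampling
    noise (per-pair sd ~ sqrt(2/n)) does not mask the thing under test —
    absence of spurious compositional correlations.
    """
    corr = np.eye(d)
    corr[0, 1] = corr[1, 0] = 0.8
    planted_tab = simulate_compositional(corr, 200, 10_000,
                                         seed=derive_seed(seed, "sp_planted"))
    r_planted = sparcc(planted_tab, seed=derive_seed(seed, "sp_fit1")).r[0, 1]
    ident_tab = simulate_compositional(np.eye(d), 2000, 10_000,
                                       seed=derive_seed(seed, "sp_ident"))
    r_ident = sparcc(ident_tab, seed=derive_seed(seed, "sp_fit2")).r
    off = r_ident[~np.eye(d, dtype=bool)]
    return {
        "planted_r": float(r_planted),
        "identity_max_abs_r": float(np.abs(off).max()),
    }
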