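"""Seeded generators for every input the comparison pipeline consumes.

The generators emulate the statistical structure the analyses assume, at
realistic scale, so every stage is testable without any download:

* a fold-change compendium (~800 datasets x ~15,000 genes) in which a
  small planted subset shares a latent injury signature with the query;
* two coupled differential-expression tables whose log2 fold changes,
  among genes significant in both, have a target Spearman correlation
  (~0.8) and a small sign-discordant fraction (<2%);
* a curated Protective/Detrimental/Ambiguous annotation with a planted
  excess of Protective genes among upregulated genes, and a predicted
  miRNA-target set planted preferentially among upregulated genes.

Effects and noise are normal on the log2 scale — the simplest model
consistent with symmetric up/down fold changes.  A single integer seed
governs everything; each generator derives its own sub-stream from a
fixed offset, so adding a generator call never perturbs earlier outputs,
and identical configurations replay byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import SimConfigError
from .io import Compendium, CuratedAnnotation, DETable, FoldChangeProfile, TargetGeneSet

# fixed sub-stream offsets: compendium, linked tables, annotation/targets
_STREAM_COMPENDIUM = 1
_STREAM_LINKED = 2
_STREAM_ANNOTATION = 3
_PILOT_SEED = 912260521  # internal stream for noise calibration, independent of cfg.seed
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic-data generators (defaults = study conditions)."""

    seed: int
    n_genes: int = 15000
    n_datasets: int = 800
    n_related: int = 5
    mixing: float = 0.6           # signature-sharing coefficient in [0, 1]
    noise_sd: float = 1.0         # per-dataset noise sd on the log2 scale
    dropout: tuple[float, float] = (0.05, 0.30)  # per-dataset missing-gene rate range
    frac_de: float = 0.15         # fraction of genes with a true shared effect
    effect_log2fc_sd: float = 2.0  # sd of true log2 fold changes of DE genes
    log2fc_se: float = 0.25       # per-table standard error of the log2FC estimate
    target_rho: float = 0.8       # Spearman target among shared significant genes
    discordance: float | None = None  # expected sign-discordance; None = natural baseline
    fdr_threshold: float = 0.05
    n_protective: int = 217
    n_detrimental: int = 199
    n_ambiguous: int = 60
    annotation_odds_ratio: float = 3.0
    target_set_size: int = 500
    target_enrichment: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.seed < 2**31:
            raise SimConfigError("seed must be a non-negative 31-bit integer")
        if not 0.0 <= self.mixing <= 1.0:
            raise SimConfigError(f"mixing={self.mixing} outside [0, 1]")
        if not 0.0 <= self.frac_de <= 1.0:
            raise SimConfigError(f"frac_de={self.frac_de} outside [0, 1]")
        if self.discordance is not None and not 0.0 <= self.discordance <= 1.0:
            raise SimConfigError(f"discordance={self.discordance} outside [0, 1]")
        if self.n_related >= self.n_datasets:
            raise SimConfigError("n_related must be smaller than n_datasets")
        if not 0.0 < self.target_rho <= 1.0:
            raise SimConfigError(
                "target_rho must lie in (0, 1]: the shared-effect + noise model "
                "cannot produce non-positive rank correlations"
            )
        for name in ("n_genes", "n_datasets", "effect_log2fc_sd", "noise_sd",
                     "n_protective", "n_detrimental", "target_set_size"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be non-negative")
        lo, hi = self.dropout
        if not 0.0 <= lo <= hi < 1.0:
            raise SimConfigError(f"dropout range {self.dropout} invalid")
        if self.annotation_odds_ratio <= 0 or self.target_enrichment <= 0:
            raise SimConfigError("planted odds ratio / enrichment must be positive")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _gene_names(n: int) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(n)])


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (the FDR used throughout)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# compendium
# ---------------------------------------------------------------------------


def generate_compendium(
    cfg: SimConfig,
) -> tuple[Compendium, FoldChangeProfile, list[str]]:
    """Simulate a fold-change compendium with a planted related subset.

    A latent standard-normal signature ``s`` is drawn per gene.  Related
    datasets and the query are ``mixing * s + noise_sd * eps`` with
    independent noise; unrelated datasets are pure noise with matching
    marginal variance.  Each dataset drops a random fraction of genes so
    query/dataset intersections vary.  Returns the compendium, the query
    profile and the ground-truth related dataset ids.
    """
    rng = _rng(cfg.seed, _STREAM_COMPENDIUM)
    genes = _gene_names(cfg.n_genes)
    s = rng.standard_normal(cfg.n_genes)
    query_vals = cfg.mixing * s + cfg.noise_sd * rng.standard_normal(cfg.n_genes)
    related_idx = set(rng.choice(cfg.n_datasets, size=cfg.n_related, replace=False).tolist())
    base_sd = math.hypot(cfg.mixing, cfg.noise_sd)
    ids = [f"DS{j:04d}" for j in range(cfg.n_datasets)]
    lo, hi = cfg.dropout
    profiles: dict[str, FoldChangeProfile] = {}
    labels = []
    for j, ds in enumerate(ids):
        if j in related_idx:
            vals = cfg.mixing * s + cfg.noise_sd * rng.standard_normal(cfg.n_genes)
            labels.append("planted")
        else:
            vals = base_sd * rng.standard_normal(cfg.n_genes)
            labels.append("background")
        rate = rng.uniform(lo, hi)
        keep = rng.random(cfg.n_genes) >= rate
        profiles[ds] = FoldChangeProfile(
            ds, species="Mus musculus", values=pd.Series(vals[keep], index=genes[keep])
        )
    meta = pd.DataFrame(
        {"species": "Mus musculus", "model": labels}, index=pd.Index(ids, name="dataset_id")
    )
    query = FoldChangeProfile(
        "QUERY", species="Mus musculus", description="planted injury signature",
        values=pd.Series(query_vals, index=genes),
    )
    related_ids = [ids[j] for j in sorted(related_idx)]
    return Compendium(profiles=profiles, metadata=meta), query, related_ids


# ---------------------------------------------------------------------------
# coupled DE tables
# ---------------------------------------------------------------------------


def _coupled_effects(
    t: float,
    delta: np.ndarray,
    de_mask: np.ndarray,
    effect_sd: float,
    se: float,
    draws: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Observed log2FC pairs for decorrelation level ``t``.

    Each DE gene's table-specific true effect is the shared effect with its
    magnitude scrambled multiplicatively (``delta * exp(eta)``, eta ~
    N(0, t^2), sign-preserving — how two injury models mostly disagree)
    plus a small additive component growing quadratically in ``t`` so low
    rank-correlation targets remain reachable.  Measurement noise with
    standard error ``se`` is added on top and drives the p-values.
    """
    gamma_sd = 0.1 * effect_sd * t * t
    ea = delta * np.exp(t * draws["eta_a"]) + gamma_sd * draws["gam_a"]
    eb = delta * np.exp(t * draws["eta_b"]) + gamma_sd * draws["gam_b"]
    ea = np.where(de_mask, ea, 0.0)
    eb = np.where(de_mask, eb, 0.0)
    return ea + se * draws["e_a"], eb + se * draws["e_b"]


def _pilot_measure(
    t: float,
    delta: np.ndarray,
    de_mask: np.ndarray,
    effect_sd: float,
    se: float,
    draws: dict[str, np.ndarray],
    requested_disc: float | None,
    fdr_threshold: float,
) -> tuple[float, float, float]:
    """Selected-set Spearman, discordance and flip rate at decorrelation t."""
    oa, ob = _coupled_effects(t, delta, de_mask, effect_sd, se, draws)
    pa = np.clip(2 * stats.norm.sf(np.abs(oa) / se), _P_FLOOR, 1.0)
    pb = np.clip(2 * stats.norm.sf(np.abs(ob) / se), _P_FLOOR, 1.0)
    sel = (benjamini_hochberg(pa) < fdr_threshold) & (benjamini_hochberg(pb) < fdr_threshold)
    if sel.sum() < 50:
        return math.nan, math.nan, 0.0
    nz = sel & (oa != 0) & (ob != 0)
    natural = float((np.sign(oa[nz]) * np.sign(ob[nz]) < 0).mean())
    q = 0.0 if requested_disc is None else max(0.0, requested_disc - natural)
    if q > 0.0:
        ob = np.where(draws["flip_u"] < q, -ob, ob)
    rho = float(stats.spearmanr(oa[sel], ob[sel]).statistic)
    disc = float((np.sign(oa[nz]) * np.sign(ob[nz]) < 0).mean())
    return rho, disc, q


@lru_cache(maxsize=32)
def _calibrate_linked(
    frac_de: float,
    effect_sd: float,
    se: float,
    target_rho: float,
    requested_disc: float | None,
    fdr_threshold: float,
) -> tuple[float, float, float]:
    """Solve for the decorrelation level by bisection against a pilot simulation.

    Selection on joint significance shifts the rank correlation, so no
    closed form applies; a fixed-seed 40,000-gene pilot measures the
    selected-set Spearman directly and the level ``t`` is bisected until
    it hits ``target_rho``.  Returns ``(t, expected discordance, flip
    rate)``.  The result depends only on the configuration, never on the
    output seed.
    """
    if target_rho >= 1.0:
        if requested_disc not in (None, 0.0):
            raise SimConfigError("target_rho=1 forces identical tables; discordance must be 0")
        return 0.0, 0.0, 0.0
    if frac_de <= 0.0 or effect_sd <= 0.0 or se <= 0.0:
        raise SimConfigError(
            "rank-correlation calibration needs frac_de > 0, effect sd > 0 and log2fc_se > 0"
        )
    rng = np.random.default_rng(_PILOT_SEED)
    n = 40000
    m = int(round(frac_de * n))
    delta = np.zeros(n)
    delta[:m] = rng.normal(0.0, effect_sd, m)
    de_mask = np.zeros(n, dtype=bool)
    de_mask[:m] = True
    draws = {
        name: rng.standard_normal(n)
        for name in ("eta_a", "eta_b", "gam_a", "gam_b", "e_a", "e_b")
    }
    draws["flip_u"] = rng.random(n)

    def rho_at(t: float) -> float:
        return _pilot_measure(
            t, delta, de_mask, effect_sd, se, draws, requested_disc, fdr_threshold
        )[0]

    # rho decreases as t grows; NaN (selection drowned) also counts as below target
    lo, hi = 0.0, 6.0
    rho_lo = rho_at(lo)
    if math.isnan(rho_lo) or rho_lo <= target_rho:
        raise SimConfigError(
            f"cannot calibrate decorrelation for target_rho={target_rho} with "
            f"frac_de={frac_de}, effect sd={effect_sd}, log2fc_se={se}"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        r_mid = rho_at(mid)
        if not math.isnan(r_mid) and r_mid > target_rho:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    rho, disc, q = _pilot_measure(
        t, delta, de_mask, effect_sd, se, draws, requested_disc, fdr_threshold
    )
    if requested_disc is not None:
        if requested_disc < disc - max(0.005, 0.3 * max(disc, 1e-9)) and q == 0.0:
            raise SimConfigError(
                f"requested discordance {requested_disc} below the achievable "
                f"baseline {disc:.4f} at target_rho={target_rho}"
            )
        if q > 0.08:
            raise SimConfigError(
                f"requested discordance {requested_disc} needs flip rate {q:.3f}, "
                f"incompatible with target_rho={target_rho}"
            )
    return t, disc, q


def generate_linked_de_tables(cfg: SimConfig) -> tuple[DETable, DETable, dict]:
    """Simulate two coupled DE tables with calibrated cross-table structure.

    A shared true log2 effect is drawn for ``frac_de`` of genes.  Each
    table observes a decorrelated copy of it: the magnitude is scrambled
    multiplicatively (sign-preserving) with a small additive component,
    at a level calibrated so the Spearman correlation among genes
    significant in both tables matches ``target_rho``; measurement noise
    with standard error ``log2fc_se`` is added on top.  P-values come
    from the stated normal model ``p = 2 * Phi(-|log2fc| / log2fc_se)``,
    with Benjamini–Hochberg FDR over each table.  Ground truth (DE genes,
    decorrelation level, flipped genes) is returned alongside.
    """
    if cfg.frac_de > 0.0:
        t, exp_disc, q = _calibrate_linked(
            cfg.frac_de, cfg.effect_log2fc_sd, cfg.log2fc_se,
            cfg.target_rho, cfg.discordance, cfg.fdr_threshold,
        )
    else:  # pure null tables: nothing to calibrate
        t, exp_disc, q = 0.0, 0.0, 0.0
    rng = _rng(cfg.seed, _STREAM_LINKED)
    n = cfg.n_genes
    genes = _gene_names(n)
    m = int(round(cfg.frac_de * n))
    de_idx = np.sort(rng.choice(n, size=m, replace=False)) if m else np.array([], dtype=int)
    de_mask = np.zeros(n, dtype=bool)
    de_mask[de_idx] = True
    delta = np.zeros(n)
    delta[de_idx] = rng.normal(0.0, cfg.effect_log2fc_sd, m)
    if cfg.target_rho >= 1.0 and cfg.frac_de > 0.0:
        # noise-free limit: identical tables, exact effects
        obs_a = delta.copy()
        obs_b = delta.copy()
        p_a = np.where(delta != 0.0, _P_FLOOR, 1.0)
        p_b = p_a.copy()
    else:
        draws = {
            name: rng.standard_normal(n)
            for name in ("eta_a", "eta_b", "gam_a", "gam_b", "e_a", "e_b")
        }
        obs_a, obs_b = _coupled_effects(
            t, delta, de_mask, cfg.effect_log2fc_sd, cfg.log2fc_se, draws
        )
        p_a = np.clip(2 * stats.norm.sf(np.abs(obs_a) / cfg.log2fc_se), _P_FLOOR, 1.0)
        p_b = np.clip(2 * stats.norm.sf(np.abs(obs_b) / cfg.log2fc_se), _P_FLOOR, 1.0)
    flip = rng.random(n) < q
    obs_b = np.where(flip, -obs_b, obs_b)
    truth = {
        "de_genes": set(genes[de_idx]),
        "decorrelation": t,
        "flip_genes": set(genes[flip]),
        "expected_discordance": exp_disc if cfg.discordance is None else cfg.discordance,
        "target_rho": cfg.target_rho,
    }
    tables = []
    for ds, obs, p in (("SIM-A", obs_a, p_a), ("SIM-B", obs_b, p_b)):
        frame = pd.DataFrame(
            {"gene": genes, "log2fc": obs, "pvalue": p, "fdr": benjamini_hochberg(p)}
        )
        tables.append(DETable(dataset_id=ds, species="Mus musculus", frame=frame))
    return tables[0], tables[1], truth


# ---------------------------------------------------------------------------
# annotation and target sets
# ---------------------------------------------------------------------------


def generate_annotation_and_targets(
    cfg: SimConfig, up: set[str], down: set[str], background: set[str]
) -> tuple[CuratedAnnotation, TargetGeneSet, dict]:
    """Plant a curated annotation and a miRNA-target set around given DE sets.

    Protective genes are drawn from the upregulated pool at odds
    ``annotation_odds_ratio`` times the background odds; Detrimental and
    Ambiguous genes at background odds.  Target genes are drawn from the
    upregulated pool at odds inflated by ``target_enrichment``.  Returns
    the annotation, the target set and the ground truth.
    """
    rng = _rng(cfg.seed, _STREAM_ANNOTATION)
    bg = sorted(background)
    up_pool = sorted(set(up) & set(bg))
    other_pool = sorted(set(bg) - set(up))
    if not up_pool or not other_pool:
        raise SimConfigError("background must contain both up and non-up genes")
    f = len(up_pool) / len(bg)
    odds_bg = f / (1.0 - f)

    def up_prob(mult: float) -> float:
        o = mult * odds_bg
        return o / (1.0 + o)

    n_ann = cfg.n_protective + cfg.n_detrimental + cfg.n_ambiguous
    if n_ann > len(bg):
        raise SimConfigError("requested annotation counts exceed available background genes")
    k_up = [
        int(rng.binomial(cfg.n_protective, up_prob(cfg.annotation_odds_ratio))),
        int(rng.binomial(cfg.n_detrimental, f)),
        int(rng.binomial(cfg.n_ambiguous, f)),
    ]
    k_other = [cfg.n_protective - k_up[0], cfg.n_detrimental - k_up[1], cfg.n_ambiguous - k_up[2]]
    if sum(k_up) > len(up_pool) or sum(k_other) > len(other_pool):
        raise SimConfigError("requested annotation counts exceed available genes in a pool")
    drawn_up = rng.choice(up_pool, size=sum(k_up), replace=False)
    drawn_other = rng.choice(other_pool, size=sum(k_other), replace=False)
    entries: dict[str, str] = {}
    iu = io_ = 0
    for label, ku, ko in zip(("Protective", "Detrimental", "Ambiguous"), k_up, k_other):
        for g in drawn_up[iu:iu + ku]:
            entries[str(g)] = label
        for g in drawn_other[io_:io_ + ko]:
            entries[str(g)] = label
        iu += ku
        io_ += ko
    annotation = CuratedAnnotation(entries)

    if cfg.target_set_size > len(bg):
        raise SimConfigError("requested target-set size exceeds available genes")
    t_up = int(rng.binomial(cfg.target_set_size, up_prob(cfg.target_enrichment)))
    if t_up > len(up_pool) or cfg.target_set_size - t_up > len(other_pool):
        raise SimConfigError("requested target-set counts exceed available genes in a pool")
    tg_up = rng.choice(up_pool, size=t_up, replace=False)
    tg_other = rng.choice(other_pool, size=cfg.target_set_size - t_up, replace=False)
    targets = TargetGeneSet(
        set_id="miR-sim-5p",
        description="synthetic predicted-target set",
        genes=frozenset(map(str, np.concatenate([tg_up, tg_other]))),
    )
    truth = {
        "annotation_odds_ratio": cfg.annotation_odds_ratio,
        "target_enrichment": cfg.target_enrichment,
        "protective_up": k_up[0],
        "detrimental_up": k_up[1],
        "targets_up": t_up,
        "background_up_fraction": f,
    }
    return annotation, targets, truth
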