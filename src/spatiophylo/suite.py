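"""End-to-end analysis: covariate preparation, model ladders, reports.

The analysis proceeds in two ladders.  First, intercept-only models
with seven random-effect combinations (phylogenetic; spatial local;
spatial regional; area blocks; and phylogenetic paired with each
spatial variant) are ranked by WAIC to pick the autocorrelation
control.  Second, seven fixed-effect models (speaker numbers,
vehicularity, their combination and interaction, neighbor counts,
official status, use in education) are fitted on top of the winning
random structure — and, for contrast, without any random effects —
to ask whether sociodemographic predictors of the complexity scores
survive the control for shared ancestry and diffusion.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .covariance import CovarianceStructure
from .errors import AlignmentError
from .model import LMMResults, ModelSpec, PCPrior, fit
from .phylo import LambdaEstimate

log = logging.getLogger(__name__)

#: the seven random-effects models of the first ladder
RANDOM_LADDER: tuple[tuple[str, ...], ...] = (
    ("phylo",),
    ("spatial_local",),
    ("spatial_regional",),
    ("areas",),
    ("phylo", "spatial_local"),
    ("phylo", "spatial_regional"),
    ("phylo", "areas"),
)

#: the seven fixed-effects models of the second ladder; the interaction
#: model holds only the product term, on the unstandardized log scale
FIXED_LADDER: tuple[tuple[str, ...], ...] = (
    ("L1_z",),
    ("vehicular",),
    ("L1_z", "vehicular"),
    ("L1_log10:vehicular",),
    ("neighbors_z",),
    ("official",),
    ("education",),
)


def egids_to_vehicular(level: int) -> int:
    """Vehicularity from an EGIDS endangerment level: 1 iff level <= 3.

    Levels 0 (International) through 3 (Wider Communication) mark
    languages expected to have L2 speakers.
    """
    level = int(level)
    if not 0 <= level <= 10:
        raise ValueError(f"EGIDS level must be in [0, 10], got {level}")
    return 1 if level <= 3 else 0


def prepare_covariates(raw: pd.DataFrame) -> pd.DataFrame:
    """Standardized covariate table from raw sociodemographic columns.

    Expects columns ``taxon`` and some of ``L1_speakers`` (raw counts),
    ``EGIDS`` (or a ready ``vehicular`` flag), ``neighbors``,
    ``official``, ``education``.  Speaker counts are floored at 1,
    log10-transformed and standardized; neighbor counts standardized;
    rows with missing modeled covariates are dropped with a logged count.
    """
    df = raw.copy()
    if "taxon" not in df.columns:
        raise ValueError("covariate table needs a 'taxon' column")
    if "L1_speakers" in df.columns:
        counts = df["L1_speakers"].astype(float)
        if (counts < 0).any():
            raise ValueError("negative speaker counts")
        floored = int((counts < 1).sum())
        if floored:
            log.info("flooring %d speaker counts at 1 before log10", floored)
        df["L1_log10"] = np.log10(counts.clip(lower=1.0))
    if "L1_log10" not in df.columns:
        raise ValueError("need L1_speakers or L1_log10")
    if "vehicular" not in df.columns:
        if "EGIDS" not in df.columns:
            raise ValueError("need EGIDS or vehicular")
        df["vehicular"] = df["EGIDS"].map(egids_to_vehicular)

    needed = ["L1_log10", "vehicular", "neighbors", "official", "education"]
    present = [c for c in needed if c in df.columns]
    before = len(df)
    df = df.dropna(subset=present)
    if len(df) < before:
        log.warning("dropped %d rows with missing covariates", before - len(df))

    def z(x):
        x = np.asarray(x, float)
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    df["L1_z"] = z(df["L1_log10"])
    if "neighbors" in df.columns:
        df["neighbors_z"] = z(df["neighbors"])
    for c in ("vehicular", "official", "education"):
        if c in df.columns:
            df[c] = df[c].astype(int)
    return df.reset_index(drop=True)


def covariate_hash(covariates: pd.DataFrame) -> str:
    """Stable digest of a covariate table (shared-preparation check)."""
    payload = covariates.round(12).to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclass
class LadderEntry:
    label: str
    spec: ModelSpec
    result: LMMResults | None = None
    error: str = ""

    @property
    def waic(self) -> float:
        return self.result.waic.waic if self.result is not None else float("inf")


@dataclass
class LadderResult:
    """Models of one ladder, ranked by ascending WAIC."""

    entries: list[LadderEntry]
    covariate_hash: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.waic)

    @property
    def best(self) -> LadderEntry:
        if not self.entries or self.entries[0].result is None:
            raise ValueError("ladder has no successful fits")
        return self.entries[0]

    @property
    def gaps(self) -> list[float]:
        w0 = self.entries[0].waic
        return [e.waic - w0 for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for entry, gap in zip(self.entries, self.gaps):
            if entry.result is None:
                rows.append({"Model": entry.label, "Effect": "<failed>",
                             "2.5%": np.nan, "50%": np.nan, "97.5%": np.nan,
                             "WAIC": np.nan, "dWAIC": np.nan,
                             "note": entry.error})
                continue
            for eff in entry.result.all_effects():
                rows.append({
                    "Model": entry.label,
                    "Effect": eff.name,
                    "2.5%": eff.q025,
                    "50%": eff.q50,
                    "97.5%": eff.q975,
                    "WAIC": entry.waic,
                    "dWAIC": gap,
                    "note": "substantial" if eff.substantial else "",
                })
        return pd.DataFrame(rows)


def _fit_ladder(specs_and_labels, scores, covariates, structures) -> list[LadderEntry]:
    entries = []
    for label, spec in specs_and_labels:
        try:
            res = fit(spec, scores, covariates, structures)
            entries.append(LadderEntry(label=label, spec=spec, result=res))
        except Exception as exc:  # a single failed fit must not stop the ladder
            log.error("model %r failed: %s", label, exc)
            entries.append(LadderEntry(label=label, spec=spec, error=str(exc)))
    return entries


def random_effects_ladder(
    scores: pd.DataFrame,
    structures: dict[str, CovarianceStructure],
    seed: int = 0,
    draws: int = 400,
    priors: dict | None = None,
    response: str = "z_score",
) -> LadderResult:
    """Rank the seven intercept-only random-effects models by WAIC."""
    combos = [c for c in RANDOM_LADDER if all(name in structures for name in c)]
    skipped = [c for c in RANDOM_LADDER if c not in combos]
    if skipped:
        log.warning("structures missing; skipping combos %s", skipped)
    jobs = []
    for combo in combos:
        spec = ModelSpec(response=response, random=combo, priors=priors,
                         seed=seed, draws=draws)
        jobs.append((" + ".join(combo), spec))
    entries = _fit_ladder(jobs, scores, None, structures)
    return LadderResult(entries, meta={"seed": seed, "draws": draws})


def fixed_effects_ladder(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    structures: dict[str, CovarianceStructure],
    best_random: tuple[str, ...],
    seed: int = 0,
    draws: int = 400,
    with_random: bool = True,
    priors: dict | None = None,
    response: str = "z_score",
) -> LadderResult:
    """Rank the seven fixed-effects models, with or without random effects."""
    random_part = tuple(best_random) if with_random else ()
    jobs = []
    for terms in FIXED_LADDER:
        spec = ModelSpec(response=response, fixed=terms, random=random_part,
                         priors=priors, seed=seed, draws=draws)
        label = " + ".join(terms)
        if random_part:
            label = f"{' + '.join(random_part)} + {label}"
        jobs.append((label, spec))
    entries = _fit_ladder(jobs, scores, covariates, structures)
    return LadderResult(
        entries,
        covariate_hash=covariate_hash(covariates),
        meta={"seed": seed, "draws": draws, "with_random": with_random},
    )


def align_taxa(*tables, tree=None) -> tuple[list[str], dict]:
    """Intersection join of taxa across tables (and a tree's tips).

    Returns the ordered common taxa and an exclusion manifest mapping
    each input to the identifiers it contributed but that were dropped.
    """
    sets = []
    names = []
    if tree is not None:
        sets.append(set(tree.tip_labels))
        names.append("tree")
    for i, t in enumerate(tables):
        col = t["taxon"] if "taxon" in t.columns else t.index
        sets.append(set(map(str, col)))
        names.append(f"table{i}")
    common = set.intersection(*sets) if sets else set()
    if len(common) < 2:
        raise AlignmentError("fewer than 2 taxa shared across inputs")
    order_source = tree.tip_labels if tree is not None else sorted(common)
    ordered = [t for t in order_source if t in common]
    manifest = {name: sorted(s - common) for name, s in zip(names, sets)}
    return ordered, manifest


def report(
    out_dir,
    ladders: dict[str, LadderResult],
    scores: pd.DataFrame | None = None,
    lambdas: dict[str, LambdaEstimate] | None = None,
    metadata: dict | None = None,
) -> list[Path]:
    """Write ranked WAIC tables, variance fractions, lambda table, metadata.

    Numeric tables are formatted with fixed precision so a rerun with
    the same seed and config is byte-identical.
    """
    if not ladders:
        raise ValueError("no ladder results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.6g")
        written.append(p)

    frac_rows = []
    for name, ladder in ladders.items():
        if not ladder.entries:
            raise ValueError(f"ladder {name!r} is empty")
        write_csv(ladder.to_frame(), f"waic_{name}.csv")
        for entry in ladder.entries:
            if entry.result is None:
                continue
            for comp, frac in entry.result.variance_partition().items():
                frac_rows.append({"ladder": name, "model": entry.label,
                                  "component": comp, "fraction": frac})
    write_csv(pd.DataFrame(frac_rows), "variance_fractions.csv")

    if scores is not None:
        write_csv(scores, "scores.csv")
    if lambdas:
        lam_rows = [
            {"metric": m, "lambda_hat": le.lambda_hat,
             "loglik_at_hat": le.loglik_at_hat,
             "loglik_at_zero": le.loglik_at_zero,
             "lrt_p": le.lrt_p, "flagged": le.flagged}
            for m, le in lambdas.items()
        ]
        write_csv(pd.DataFrame(lam_rows), "lambda.csv")

    meta = dict(metadata or {})
    meta.setdefault("package_version", __version__)
    meta["ladders"] = {
        name: {"best": lad.entries[0].label, "seed": lad.meta.get("seed"),
               "covariate_hash": lad.covariate_hash or None}
        for name, lad in ladders.items()
    }
    cfg_digest = hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()
    meta["config_hash"] = cfg_digest
    p = out / "run_metadata.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    written.append(p)
    return written


def default_priors(alpha: float = 0.1, u: float = 1.0) -> dict:
    """PC priors at P(sigma > u) = alpha for every SD in a model."""
    return {"default": PCPrior(u=u, alpha=alpha)}
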