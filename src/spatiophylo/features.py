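"""Binary typological feature tables and grammatical-complexity scores.

Two scores are supported through a shared mechanism, configured by a
:class:`MetricDefinition`:

* **fusion** — the share of grammatical functions a language marks with
  phonologically bound (affixal) material; typically every feature is
  its own function-group.
* **informativity** — the share of grammatical functions marked
  explicitly and obligatorily at all; features describing fused and
  independent exponents of the *same* function are placed in one group,
  and the group counts once if any member is present (OR rule).

Per taxon, each group contributes 1 if any member feature is present,
0 if all coded members are absent, and is skipped when every member is
missing; the raw score is the mean over non-skipped groups, hence lies
in [0, 1].  Taxa with more than a configurable fraction of missing
values across *all* features in the table (default 25%, strict) are
removed before scoring.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DefinitionError,
    DegenerateInputError,
    FormatError,
    IntegrityError,
)

log = logging.getLogger(__name__)

PRESENT = 1.0
ABSENT = 0.0
MISSING = np.nan

#: default cell-value mapping; anything else falls back to
#: present-if-nonzero with a logged count (multistate questions).
DEFAULT_VALUE_MAP = {
    "1": PRESENT,
    "0": ABSENT,
    "1.0": PRESENT,
    "0.0": ABSENT,
    "?": MISSING,
    "": MISSING,
    "NA": MISSING,
    "na": MISSING,
    "nan": MISSING,
}


@dataclass
class FeatureMatrix:
    """Taxa x binary features with an explicit missing state.

    ``data`` holds floats in {1.0, 0.0, NaN} with taxa as the index and
    feature identifiers as columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise IntegrityError("duplicate taxon identifiers")
        if self.data.columns.duplicated().any():
            raise IntegrityError("duplicate feature identifiers")
        vals = self.data.to_numpy(float)
        ok = np.isnan(vals) | (vals == PRESENT) | (vals == ABSENT)
        if not ok.all():
            raise IntegrityError("entries must be present (1), absent (0) or missing")

    @property
    def taxa(self) -> list[str]:
        return [str(t) for t in self.data.index]

    @property
    def features(self) -> list[str]:
        return [str(f) for f in self.data.columns]

    def missing_fraction(self) -> pd.Series:
        """Per-taxon fraction of missing entries over all features."""
        return self.data.isna().mean(axis=1)


def _map_values(raw: pd.DataFrame, value_map: dict | None) -> pd.DataFrame:
    vmap = dict(DEFAULT_VALUE_MAP)
    if value_map:
        vmap.update({str(k): v for k, v in value_map.items()})
    flat = raw.astype(str).apply(lambda col: col.str.strip())
    unknown = 0

    def convert(x: str) -> float:
        nonlocal unknown
        if x in vmap:
            return vmap[x]
        try:
            num = float(x)
        except ValueError:
            raise FormatError(f"unparseable feature value {x!r}") from None
        unknown += 1
        return PRESENT if num != 0 else ABSENT

    out = flat.map(convert)
    if unknown:
        log.warning(
            "%d cell(s) outside the value map coerced present-if-nonzero", unknown
        )
    return out


def read_feature_table(
    path,
    dialect: str = "wide_csv",
    value_map: dict | None = None,
) -> FeatureMatrix:
    """Read a feature table in wide or CLDF-style long CSV layout.

    ``wide_csv``: first column is the taxon identifier, remaining
    columns are features, cells in {1, 0, ?, empty}.  ``cldf_long``:
    columns Language_ID, Parameter_ID, Value (one row per coded cell).
    """
    path = str(path)
    if dialect == "wide_csv":
        with open(path, newline="") as fh:
            header = next(csv.reader(fh))
        feats = header[1:]
        if len(set(feats)) != len(feats):
            raise IntegrityError("duplicate feature columns in wide table")
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        if raw.empty:
            raise FormatError(f"no rows in {path}")
        taxa = raw.iloc[:, 0]
        if taxa.duplicated().any():
            raise IntegrityError(
                f"duplicate taxon rows: {sorted(taxa[taxa.duplicated()].unique())}"
            )
        body = raw.iloc[:, 1:]
        body.index = pd.Index(taxa, name="taxon")
        return FeatureMatrix(_map_values(body, value_map))
    if dialect == "cldf_long":
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        cols = {c.lower(): c for c in raw.columns}
        try:
            lang = cols.get("language_id", cols.get("taxon"))
            param = cols.get("parameter_id", cols.get("feature"))
            value = cols.get("value")
            assert lang and param and value
        except AssertionError:
            raise FormatError(
                "long table needs Language_ID, Parameter_ID, Value columns"
            ) from None
        dup = raw.duplicated(subset=[lang, param])
        if dup.any():
            pairs = raw.loc[dup, [lang, param]].head().to_records(index=False)
            raise IntegrityError(f"repeated (taxon, feature) rows: {list(pairs)}")
        wide = raw.pivot(index=lang, columns=param, values=value)
        wide = wide.fillna("")  # cells absent from the long table are missing
        wide.index.name = "taxon"
        return FeatureMatrix(_map_values(wide, value_map))
    raise ValueError(f"unknown dialect {dialect!r}")


@dataclass
class MetricDefinition:
    """A named metric: function-groups of features plus exclusions."""

    name: str
    groups: dict[str, list[str]]
    excluded_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.groups:
            raise DefinitionError(f"metric {self.name!r} has no groups")
        seen: dict[str, str] = {}
        for gname, members in self.groups.items():
            if not members:
                raise DefinitionError(f"group {gname!r} is empty")
            for f in members:
                if f in seen:
                    raise DefinitionError(
                        f"feature {f!r} in groups {seen[f]!r} and {gname!r}"
                    )
                if f in self.excluded_features:
                    raise DefinitionError(f"feature {f!r} both used and excluded")
                seen[f] = gname

    @classmethod
    def from_json(cls, path) -> "MetricDefinition":
        with open(path) as fh:
            cfg = json.load(fh)
        return cls(
            name=cfg["name"],
            groups={g: list(m) for g, m in cfg["groups"].items()},
            excluded_features=list(cfg.get("excluded_features", [])),
        )

    @classmethod
    def singleton(cls, name: str, features, excluded=()) -> "MetricDefinition":
        """One group per feature — the fusion-style definition."""
        feats = [f for f in features if f not in set(excluded)]
        return cls(name=name, groups={f: [f] for f in feats},
                   excluded_features=list(excluded))


def example_definition(name: str) -> MetricDefinition:
    """Load a bundled toy metric definition: "fusion" or "informativity".

    These document the expected configuration layout (function-groups
    and exclusions); real analyses supply their own definition files
    derived from the published feature lists.
    """
    from importlib import resources

    ref = resources.files("spatiophylo") / "data" / f"{name}_toy.json"
    with resources.as_file(ref) as path:
        return MetricDefinition.from_json(path)


def apply_coverage_filter(m: FeatureMatrix, max_missing: float = 0.25) -> FeatureMatrix:
    """Drop taxa with *more than* ``max_missing`` missing over all features.

    The boundary is strict: a taxon with exactly ``max_missing`` missing
    is retained.  Row order of the survivors is preserved.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    frac = m.missing_fraction()
    keep = frac <= max_missing + 1e-12
    dropped = int((~keep).sum())
    if dropped:
        log.info("coverage filter removed %d taxa (> %.0f%% missing)",
                 dropped, 100 * max_missing)
    if not keep.any():
        log.warning("coverage filter removed every taxon")
    return FeatureMatrix(m.data.loc[keep])


def score_metric(m: FeatureMatrix, definition: MetricDefinition) -> pd.DataFrame:
    """Raw metric scores: mean over function-groups of the OR indicator.

    Returns a score table with columns ``taxon, metric, raw_score,
    n_groups_coded`` (``z_score`` is added by :func:`standardize`).
    Taxa whose groups are all missing are dropped with a log entry.
    """
    unknown = [
        f for members in definition.groups.values() for f in members
        if f not in m.data.columns
    ]
    if unknown:
        raise DefinitionError(
            f"metric {definition.name!r} references unknown features: {unknown[:5]}"
        )
    n = len(m.data)
    group_scores = np.full((n, len(definition.groups)), np.nan)
    for j, members in enumerate(definition.groups.values()):
        block = m.data[members].to_numpy(float)
        any_present = np.nansum(block == PRESENT, axis=1) > 0
        any_coded = (~np.isnan(block)).any(axis=1)
        col = np.where(any_present, 1.0, np.where(any_coded, 0.0, np.nan))
        group_scores[:, j] = col
    n_coded = (~np.isnan(group_scores)).sum(axis=1)
    totals = np.nansum(group_scores, axis=1)
    raw = np.divide(totals, n_coded, out=np.full(n, np.nan), where=n_coded > 0)
    table = pd.DataFrame(
        {
            "taxon": m.taxa,
            "metric": definition.name,
            "raw_score": raw,
            "n_groups_coded": n_coded,
        }
    )
    uncoded = table["n_groups_coded"] == 0
    if uncoded.any():
        log.info("dropping %d taxa with no coded groups for metric %r",
                 int(uncoded.sum()), definition.name)
        table = table.loc[~uncoded].reset_index(drop=True)
    return table


def standardize(s: pd.DataFrame, column: str = "raw_score") -> pd.DataFrame:
    """Add ``z_score`` = (raw - mean) / sd, sample (n-1) denominator."""
    if len(s) < 2:
        raise DegenerateInputError("need at least 2 taxa to standardize")
    raw = s[column].to_numpy(float)
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("scores have zero variance")
    out = s.copy()
    out["z_score"] = (raw - raw.mean()) / sd
    return out


def score_pipeline(
    m: FeatureMatrix,
    definitions,
    max_missing: float = 0.25,
) -> pd.DataFrame:
    """Filter coverage, score each metric, and standardize; long output."""
    filtered = apply_coverage_filter(m, max_missing)
    tables = [standardize(score_metric(filtered, d)) for d in definitions]
    return pd.concat(tables, ignore_index=True)
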