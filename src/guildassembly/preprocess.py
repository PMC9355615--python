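"""Rarefaction, variable transformation, and community-weighted trait means."""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .errors import ValidationError
from .tabular_io import OtuTable

__all__ = ["TransformScheme", "DEFAULT_TRANSFORMS", "rarefy",
           "apply_transforms", "community_weighted_mean"]


@dataclass(frozen=True)
class TransformScheme:
    """Named variables to square-root or log10 transform before analysis."""

    sqrt_vars: frozenset[str] = frozenset()
    log10_vars: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sqrt_vars", frozenset(self.sqrt_vars))
        object.__setattr__(self, "log10_vars", frozenset(self.log10_vars))
        overlap = self.sqrt_vars & self.log10_vars
        if overlap:
            raise ValidationError(
                f"variables in both sqrt and log10 sets: {sorted(overlap)}")


# Analysis-scale conventions: soil moisture/salts/available N+P on sqrt scale,
# size-like leaf and root attributes on log10 scale.
DEFAULT_TRANSFORMS = TransformScheme(
    sqrt_vars=frozenset({"SM", "SEC", "SAP", "NH4N", "NO3N"}),
    log10_vars=frozenset({"LA", "SLA", "RL", "SRL", "RNC"}),
)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per sample; zero cells stay zero,
    all OTU columns are retained, and the draw is reproducible under seed.
    """
    if depth <= 0:
        raise ValidationError(f"rarefaction depth must be positive, got {depth}")
    sums = table.row_sums()
    short = [(table.sample_ids[i], int(sums[i]))
             for i in np.flatnonzero(sums < depth)]
    if short:
        listing = ", ".join(f"{s}={n}" for s, n in short[:5])
        raise ValidationError(
            f"rarefaction depth {depth} exceeds sample totals: {listing}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        row = table.counts[i]
        if sums[i] == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(table.sample_ids, table.otu_ids, out)


def apply_transforms(df: pd.DataFrame, scheme: TransformScheme) -> pd.DataFrame:
    """Replace named columns by sqrt / log10 values; others untouched.

    Errors name the offending variable and sample. The applied scheme is
    recorded in ``result.attrs['transforms']``.
    """
    out = df.copy()
    applied: dict[str, str] = {}
    for var in sorted(scheme.sqrt_vars):
        if var not in out.columns:
            continue
        col = out[var].astype(float)
        bad = col.index[col < 0]
        if len(bad):
            raise ValidationError(
                f"negative value under sqrt transform: variable {var!r}, "
                f"sample {bad[0]!r}")
        out[var] = np.sqrt(col)
        applied[var] = "sqrt"
    for var in sorted(scheme.log10_vars):
        if var not in out.columns:
            continue
        col = out[var].astype(float)
        bad = col.index[col <= 0]
        if len(bad):
            raise ValidationError(
                f"non-positive value under log10 transform: variable {var!r}, "
                f"sample {bad[0]!r}")
        out[var] = np.log10(col)
        applied[var] = "log10"
    out.attrs["transforms"] = applied
    return out


def community_weighted_mean(community: pd.DataFrame, traits: pd.DataFrame,
                            trait: str) -> pd.Series:
    """CWM = sum_n P_n * Trait_n per quadrat.

    ``community`` is quadrats x species relative abundances (rows sum to 1);
    ``traits`` is long format indexed by (quadrat_id, species). A species
    with positive abundance but no trait value raises — never silently drops.
    """
    if trait not in traits.columns:
        raise ValidationError(f"trait {trait!r} not present in trait table")
    sums = community.sum(axis=1)
    bad = sums.index[np.abs(sums.values - 1.0) > 1e-6]
    if len(bad):
        raise ValidationError(
            f"community rows do not sum to 1: {list(bad[:3])}")
    values = {}
    for quadrat, row in community.iterrows():
        present = row[row > 0]
        acc = 0.0
        for species, p in present.items():
            try:
                t = traits.loc[(str(quadrat), str(species)), trait]
            except KeyError:
                raise ValidationError(
                    f"species {species!r} (abundance {p:.3g}) lacks trait "
                    f"{trait!r} in quadrat {quadrat!r}") from None
            if pd.isna(t):
                raise ValidationError(
                    f"species {species!r} has missing value for trait "
                    f"{trait!r} in quadrat {quadrat!r}")
            acc += float(p) * float(t)
        values[quadrat] = acc
    return pd.Series(values, name=f"CWM_{trait}")
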