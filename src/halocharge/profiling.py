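"""Per-strain charge profiles, cluster-vs-proteome comparison, trend tests.

This module turns raw proteomes plus strain metadata into the quantities the
charge analysis is about:

* a :class:`StrainProfile` — net charge (default pH 7.4) of every S10-spc
  cluster r-protein found in a proteome, the count of members below the
  acidity cutoff (default 3), and the strain's halotolerance class;
* a :class:`ProteomeComparison` — summary charge statistics of the cluster
  members versus the rest of the proteome;
* a :class:`TrendReport` — Spearman rank correlations between a strain's
  salt ranking and (a) its acidic-member count and (b) its mean cluster
  charge, with permutation p-values (the relationship itself is assessed
  qualitatively in the source analyses; the statistic is this package's own
  quantification);
* :func:`always_basic_check` — the members that stay at or above the cutoff
  in every profile (empirically, only uL2 on real data);
* :func:`render_profiles` — the two-colour heatmap and per-strain bar
  charts mirroring the usual presentation of these profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ClusterRoster, extract_cluster_proteins, roster_for, roster_order
from .charge import (
    ACIDITY_CUTOFF,
    DEFAULT_PH,
    DEFAULT_SCALE,
    ChargeResult,
    PkaScale,
    ProteinSequence,
    charge_result,
    classify_acidity,
    display_charge,
    net_charge,
)
from .halotolerance import HalotoleranceClass, StrainMetadata, salt_score

__all__ = [
    "StrainProfile",
    "ProteomeComparison",
    "TrendReport",
    "profile_strain",
    "compare_cluster_vs_proteome",
    "trend_summary",
    "always_basic_check",
    "charge_table",
    "render_profiles",
]


@dataclass
class StrainProfile:
    """One organism's S10-spc cluster charge profile."""

    strain_id: str
    domain: str
    halotolerance_class: Optional[HalotoleranceClass]
    charges: dict[str, ChargeResult]
    n_found: int
    n_acidic: int
    missing: list[str]
    cutoff: float = ACIDITY_CUTOFF
    salt_score: Optional[float] = None

    @property
    def mean_charge(self) -> float:
        return float(np.mean([c.net_charge for c in self.charges.values()]))

    @property
    def median_charge(self) -> float:
        return float(np.median([c.net_charge for c in self.charges.values()]))


@dataclass
class ProteomeComparison:
    """Cluster-vs-rest charge summary for one strain.

    Mean and median are both reported because halophile charge
    distributions are skewed.
    """

    strain_id: str
    cluster_mean_charge: float
    cluster_median_charge: float
    rest_mean_charge: float
    rest_median_charge: float
    fraction_rest_negative: float
    n_cluster: int
    n_rest: int


def profile_strain(
    proteome: Iterable[ProteinSequence],
    metadata: StrainMetadata,
    ph: float = DEFAULT_PH,
    scale: Union[str, PkaScale] = DEFAULT_SCALE,
    cutoff: float = ACIDITY_CUTOFF,
    roster: Optional[ClusterRoster] = None,
) -> StrainProfile:
    """Compute the cluster charge profile of one annotated proteome."""
    if roster is None:
        roster = roster_for(metadata.domain)
    extraction = extract_cluster_proteins(proteome, roster)
    charges = {
        name: charge_result(seq, ph=ph, scale=scale, cutoff=cutoff)
        for name, seq in extraction.proteins.items()
    }
    n_acidic = sum(1 for c in charges.values() if c.acidity_label == "acidic")
    try:
        klass = metadata.effective_class()
    except ValueError:
        klass = None
    return StrainProfile(
        strain_id=metadata.strain_id,
        domain=metadata.domain,
        halotolerance_class=klass,
        charges=charges,
        n_found=extraction.n_found,
        n_acidic=n_acidic,
        missing=extraction.missing,
        cutoff=cutoff,
        salt_score=salt_score(metadata.salt),
    )


def compare_cluster_vs_proteome(
    proteome: Iterable[ProteinSequence],
    cluster_ids: Iterable[str],
    ph: float = DEFAULT_PH,
    scale: Union[str, PkaScale] = DEFAULT_SCALE,
    strain_id: str = "",
) -> ProteomeComparison:
    """Compare charges of cluster records against the rest of the proteome.

    ``cluster_ids`` are record ids (not universal names); the two partitions
    are disjoint by construction and the rest partition must be non-empty.
    """
    cluster_ids = set(cluster_ids)
    cluster_z, rest_z = [], []
    for record in proteome:
        z = net_charge(record, ph, scale)
        (cluster_z if record.id in cluster_ids else rest_z).append(z)
    if not cluster_z:
        raise ValueError("no cluster records found in proteome")
    if not rest_z:
        raise ValueError("empty rest partition: proteome contains only cluster records")
    rest = np.asarray(rest_z)
    return ProteomeComparison(
        strain_id=strain_id,
        cluster_mean_charge=float(np.mean(cluster_z)),
        cluster_median_charge=float(np.median(cluster_z)),
        rest_mean_charge=float(rest.mean()),
        rest_median_charge=float(np.median(rest)),
        fraction_rest_negative=float((rest < 0).mean()),
        n_cluster=len(cluster_z),
        n_rest=len(rest_z),
    )


@dataclass
class TrendReport:
    """Rank-correlation summary of the salt-vs-charge relationship."""

    n_strains: int
    salt_variable: str
    rho_n_acidic: float
    p_n_acidic: float
    rho_mean_charge: float
    p_mean_charge: float
    n_permutations: int
    seed: int
    degenerate: bool = False
    per_protein: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def to_dict(self) -> dict:
        out = {
            "n_strains": self.n_strains,
            "salt_variable": self.salt_variable,
            "rho_n_acidic": None if np.isnan(self.rho_n_acidic) else self.rho_n_acidic,
            "p_n_acidic": None if np.isnan(self.p_n_acidic) else self.p_n_acidic,
            "rho_mean_charge": None if np.isnan(self.rho_mean_charge) else self.rho_mean_charge,
            "p_mean_charge": None if np.isnan(self.p_mean_charge) else self.p_mean_charge,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }
        if len(self.per_protein):
            out["per_protein"] = self.per_protein.to_dict(orient="records")
        return out


def _spearman_with_permutation(
    x: np.ndarray, y: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Spearman rho plus a two-sided permutation p-value.

    The observed rho comes from scipy; the null is built by permuting the
    ranks of ``y`` wholesale, which keeps ties intact.
    """
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    xr_c = xr - xr.mean()
    yr_c = yr - yr.mean()
    denom = np.sqrt((xr_c**2).sum() * (yr_c**2).sum())
    perms = rng.permuted(np.tile(yr_c, (n_permutations, 1)), axis=1)
    rho_null = perms @ xr_c / denom
    p = (1.0 + np.sum(np.abs(rho_null) >= abs(rho) - 1e-12)) / (n_permutations + 1.0)
    return rho, float(p)


def trend_summary(
    profiles: Sequence[StrainProfile],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> TrendReport:
    """Quantify how cluster charges track the strains' salt ranking.

    Spearman rank correlation of (salt ranking, n_acidic) and (salt
    ranking, mean cluster charge) with a seeded permutation null.  The salt
    ranking is the maximum stated salt concentration when every strain has
    one, else the class ordinal.  An inverse charge-halotolerance
    relationship shows up as ``rho_mean_charge < 0`` (and
    ``rho_n_acidic > 0``).  Requires at least three profiles spanning at
    least two classes; constant inputs yield NaN correlations flagged
    ``degenerate``.
    """
    if len(profiles) < 3:
        raise ValueError("trend_summary needs at least 3 strain profiles")
    classes = {p.halotolerance_class for p in profiles}
    if len(classes - {None}) < 2:
        raise ValueError("trend_summary needs profiles spanning at least 2 classes")

    if all(p.salt_score is not None for p in profiles):
        x = np.array([p.salt_score for p in profiles], dtype=float)
        salt_variable = "max_salt_pct"
    else:
        x = np.array(
            [p.halotolerance_class.ordinal if p.halotolerance_class else np.nan for p in profiles]
        )
        salt_variable = "class_ordinal"
    n_acidic = np.array([p.n_acidic for p in profiles], dtype=float)
    mean_charge = np.array([p.mean_charge for p in profiles], dtype=float)

    rng = np.random.default_rng(seed)
    rho_a, p_a = _spearman_with_permutation(x, n_acidic, n_permutations, rng)
    rho_m, p_m = _spearman_with_permutation(x, mean_charge, n_permutations, rng)

    rows = []
    members = roster_order({m for p in profiles for m in p.charges})
    for m in members:
        zs = [p.charges[m].net_charge for p in profiles if m in p.charges]
        labels = [classify_acidity(z, profiles[0].cutoff) for z in zs]
        rows.append(
            {
                "protein": m,
                "n_profiles": len(zs),
                "min_charge": min(zs),
                "max_charge": max(zs),
                "n_acidic": labels.count("acidic"),
            }
        )
    return TrendReport(
        n_strains=len(profiles),
        salt_variable=salt_variable,
        rho_n_acidic=rho_a,
        p_n_acidic=p_a,
        rho_mean_charge=rho_m,
        p_mean_charge=p_m,
        n_permutations=n_permutations,
        seed=seed,
        degenerate=bool(np.isnan(rho_a) or np.isnan(rho_m)),
        per_protein=pd.DataFrame(rows),
    )


def always_basic_check(
    profiles: Sequence[StrainProfile], cutoff: float = ACIDITY_CUTOFF
) -> list[str]:
    """Members whose charge is >= cutoff in every profile (exact intersection).

    A member missing from a profile is not basic there and drops out.
    """
    if not profiles:
        raise ValueError("always_basic_check needs at least one profile")
    basic_sets = [
        {m for m, c in p.charges.items() if c.net_charge >= cutoff} for p in profiles
    ]
    result = set.intersection(*basic_sets)
    return roster_order(result)


def charge_table(profiles: Sequence[StrainProfile]) -> pd.DataFrame:
    """Strains x members matrix of net charges (NaN where missing).

    This is the exact data table behind the heatmap; colour assignment in
    the figure equals :func:`classify_acidity` applied to these cells.
    """
    members = roster_order({m for p in profiles for m in p.charges} |
                           {m for p in profiles for m in p.missing})
    data = {
        p.strain_id: [
            p.charges[m].net_charge if m in p.charges else np.nan for m in members
        ]
        for p in profiles
    }
    return pd.DataFrame(data, index=members).T


def render_profiles(
    profiles: Sequence[StrainProfile],
    out_dir: Union[str, Path],
    cutoff: float = ACIDITY_CUTOFF,
    fmt: str = "png",
) -> list[Path]:
    """Write the two-colour cluster heatmap and one bar chart per strain.

    Heatmap cells are red at/above the cutoff and yellow below it (the
    conventional display for these profiles); missing members render grey,
    never as zero.  Bar charts label each bar with its rounded charge.
    Returns the created paths; file naming is deterministic.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    if not profiles:
        raise ValueError("render_profiles needs at least one profile")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    table = charge_table(profiles)
    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.4 * table.shape[1]), max(2.5, 0.4 * table.shape[0]))
    )
    cmap = ListedColormap(["gold", "red"])
    cmap.set_bad("lightgrey")
    # two colour classes: below cutoff vs at/above cutoff
    norm = BoundaryNorm([-np.inf, cutoff, np.inf], cmap.N)
    masked = np.ma.masked_invalid(table.to_numpy())
    ax.imshow(masked, cmap=cmap, norm=norm, aspect="auto", interpolation="nearest")
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(table.shape[0]), table.index, fontsize=7)
    ax.set_title(f"S10-spc cluster net charges (red >= {cutoff:g}, yellow < {cutoff:g})")
    fig.tight_layout()
    heatmap_path = out_dir / f"cluster_heatmap.{fmt}"
    fig.savefig(heatmap_path, dpi=150)
    plt.close(fig)
    created.append(heatmap_path)

    for profile in profiles:
        members = roster_order(set(profile.charges) | set(profile.missing))
        values = [
            profile.charges[m].net_charge if m in profile.charges else np.nan for m in members
        ]
        colors = [
            "lightgrey" if np.isnan(v) else ("red" if v >= cutoff else "black") for v in values
        ]
        fig, ax = plt.subplots(figsize=(max(6.0, 0.35 * len(members)), 3.2))
        ax.bar(range(len(members)), [0 if np.isnan(v) else v for v in values], color=colors)
        for i, v in enumerate(values):
            if np.isnan(v):
                ax.text(i, 0.3, "n/a", ha="center", fontsize=6, color="grey", rotation=90)
            else:
                ax.text(i, v, str(display_charge(v)), ha="center",
                        va="bottom" if v >= 0 else "top", fontsize=6)
        ax.axhline(cutoff, lw=0.8, ls="--", color="grey")
        ax.axhline(0, lw=0.8, color="black")
        ax.set_xticks(range(len(members)), members, rotation=90, fontsize=7)
        ph = next(iter(profile.charges.values())).ph if profile.charges else DEFAULT_PH
        ax.set_ylabel(f"net charge (pH {ph:g})")
        label = profile.halotolerance_class.value if profile.halotolerance_class else "unclassified"
        ax.set_title(f"{profile.strain_id} ({label}); acidic {profile.n_acidic}/{profile.n_found}")
        fig.tight_layout()
        path = out_dir / f"charges_{_safe_name(profile.strain_id)}.{fmt}"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        created.append(path)
    return created


def _safe_name(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)
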