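"""PSI scoring of FACS-seq stability screens and the E3 delta-PSI analysis.

A screen sorts a GFP-peptide fusion library into four fluorescence gates
(G1 = least fluorescent / least stable ... G4 = most stable) holding equal
cell numbers, then sequences each gate. The Protein Stability Index of
peptide i is the gate-index-weighted mean of its read frequencies:

    PSI_i = sum_g g * f_ig / sum_g f_ig,   f_ig = count_ig / depth_g

so PSI ranges from 1 (all reads in the bottom gate, maximally unstable) to
4 (maximally stable). Frequencies rather than raw counts make the score
invariant to per-gate sequencing depth.

The module also implements the knockout comparison: for each E3-ligase
deletion strain, delta-PSI = PSI_knockout - PSI_control per control degron,
with a peptide called "stabilized" when its delta-PSI exceeds the strain's
mean + 2 standard errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("degronscan")

GATE_COLUMNS = ["G1", "G2", "G3", "G4"]
GATE_INDICES = np.array([1.0, 2.0, 3.0, 4.0])

#: Default thresholds (PSI units unless noted).
MIN_READS = 50            # keep peptides with total reads strictly > this
UNSTABLE_MAX = 2.2        # training label: unstable if PSI < 2.2
STABLE_MIN = 2.8          # training label: stable if PSI > 2.8
DEGRON_CUTOFF = 1.7       # degron call: PSI < 1.7
HIGH_CONF_CUTOFF = 1.62   # high-confidence degron call: PSI <= 1.62
TOP_FRACTION = 0.10       # top delta-PSI fraction compared across strains


class CountTableError(ValueError):
    pass


@dataclass
class GateCountTable:
    """Per-peptide read counts across the four sort gates for one strain."""

    counts: pd.DataFrame
    strain: str = "control"

    def __post_init__(self) -> None:
        missing = [c for c in ["peptide_id", *GATE_COLUMNS]
                   if c not in self.counts.columns]
        if missing:
            raise CountTableError(f"missing columns: {missing}")
        if self.counts["peptide_id"].duplicated().any():
            dups = self.counts.loc[
                self.counts["peptide_id"].duplicated(), "peptide_id"
            ].unique()
            raise CountTableError(
                f"duplicate peptide ids: {', '.join(map(str, dups[:5]))}"
            )
        if (self.counts[GATE_COLUMNS].to_numpy() < 0).any():
            raise CountTableError("negative gate counts")

    def __len__(self) -> int:
        return len(self.counts)

    @classmethod
    def from_tsv(cls, path, strain: str | None = None) -> "GateCountTable":
        """Load a TSV with columns peptide_id, [sequence,] G1..G4.

        The strain label defaults to the file stem.
        """
        df = pd.read_csv(path, sep="\t")
        if strain is None:
            from pathlib import Path
            strain = Path(path).stem
        return cls(counts=df, strain=strain)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def drop_ambiguous(table: GateCountTable) -> GateCountTable:
    """Drop peptides whose sequence maps to more than one library member.

    Ambiguous DNA tiles (identical peptide sequence at several library
    positions) cannot be attributed to a single source, so every row
    sharing such a sequence is removed. Requires a ``sequence`` column;
    tables without one are returned unchanged.
    """
    df = table.counts
    if "sequence" not in df.columns:
        return table
    multi = df["sequence"].duplicated(keep=False)
    if multi.any():
        logger.info("drop_ambiguous[%s]: removed %d rows with shared sequences",
                    table.strain, int(multi.sum()))
    return GateCountTable(counts=df.loc[~multi].reset_index(drop=True),
                          strain=table.strain)


def filter_low_coverage(table: GateCountTable,
                        min_reads: int = MIN_READS) -> GateCountTable:
    """Keep peptides with total reads across the 4 gates strictly > min_reads."""
    totals = table.counts[GATE_COLUMNS].sum(axis=1)
    kept = table.counts.loc[totals > min_reads].reset_index(drop=True)
    logger.info("filter_low_coverage[%s]: kept %d / %d peptides (> %d reads)",
                table.strain, len(kept), len(table.counts), min_reads)
    return GateCountTable(counts=kept, strain=table.strain)


def normalize_gates(table: GateCountTable) -> pd.DataFrame:
    """Convert raw counts to within-gate frequencies f_ig = count / depth_g.

    Gates are sorted to equal cell numbers but sequenced to unequal depth,
    so frequencies, not counts, measure a peptide's share of a gate. A gate
    with zero total reads contributes f_ig = 0 for every peptide.

    Returns a DataFrame indexed like the input with columns G1..G4.

    Raises
    ------
    CountTableError
        If all four gate totals are zero.
    """
    counts = table.counts[GATE_COLUMNS].to_numpy(dtype=float)
    depths = counts.sum(axis=0)
    if (depths == 0).all():
        raise CountTableError(f"{table.strain}: all gate totals are zero")
    safe = np.where(depths > 0, depths, 1.0)
    freqs = counts / safe
    freqs[:, depths == 0] = 0.0
    return pd.DataFrame(freqs, columns=GATE_COLUMNS,
                        index=table.counts.index)


def compute_psi(table: GateCountTable) -> pd.DataFrame:
    """Score each peptide's stability from its gate read distribution.

    Returns a PSI table: peptide_id, psi (in [1, 4]), total_reads. Peptides
    with zero frequency in every gate cannot be scored and are dropped with
    a logged count. Sequence is carried through when present.
    """
    freqs = normalize_gates(table).to_numpy()
    fsum = freqs.sum(axis=1)
    scored = fsum > 0
    n_dropped = int((~scored).sum())
    if n_dropped:
        logger.info("compute_psi[%s]: dropped %d unscorable peptides",
                    table.strain, n_dropped)
    psi = (freqs[scored] @ GATE_INDICES) / fsum[scored]
    out = pd.DataFrame({
        "peptide_id": table.counts.loc[scored, "peptide_id"].to_numpy(),
        "psi": psi,
        "total_reads": table.counts.loc[scored, GATE_COLUMNS]
                       .sum(axis=1).to_numpy(),
    })
    if "sequence" in table.counts.columns:
        out.insert(1, "sequence", table.counts.loc[scored, "sequence"].to_numpy())
    return out


def label_for_training(psi_table: pd.DataFrame,
                       unstable_max: float = UNSTABLE_MAX,
                       stable_min: float = STABLE_MIN) -> pd.DataFrame:
    """Attach training labels and return the labeled (non-intermediate) subset.

    Peptides with PSI below ``unstable_max`` are labeled ``unstable``
    (degron class), those above ``stable_min`` are ``stable``; the
    mid-band is ``intermediate`` and excluded from the returned frame.
    The full labeling (including intermediates) is recorded in a ``label``
    column added to the input copy.
    """
    if unstable_max >= stable_min:
        raise ValueError(
            f"unstable_max ({unstable_max}) must be < stable_min ({stable_min})"
        )
    out = psi_table.copy()
    out["label"] = "intermediate"
    out.loc[out["psi"] < unstable_max, "label"] = "unstable"
    out.loc[out["psi"] > stable_min, "label"] = "stable"
    return out.loc[out["label"] != "intermediate"].reset_index(drop=True)


def call_degrons(psi_table: pd.DataFrame,
                 cutoff: float = DEGRON_CUTOFF,
                 inclusive: bool = False) -> tuple[set, float]:
    """Call degrons from PSI scores.

    Returns the set of degron peptide ids and the fraction of scored
    peptides called. The default comparator is strict (PSI < cutoff);
    ``inclusive=True`` uses PSI <= cutoff, the convention used for
    high-confidence calls at 1.62.
    """
    psi = psi_table["psi"]
    mask = psi <= cutoff if inclusive else psi < cutoff
    ids = set(psi_table.loc[mask, "peptide_id"])
    return ids, float(mask.mean()) if len(psi_table) else 0.0


def annotate_psi(psi_table: pd.DataFrame,
                 unstable_max: float = UNSTABLE_MAX,
                 stable_min: float = STABLE_MIN,
                 degron_cutoff: float = DEGRON_CUTOFF,
                 inclusive_degron: bool = False) -> pd.DataFrame:
    """Full PSI annotation: label column plus an is_degron flag."""
    out = psi_table.copy()
    out["label"] = "intermediate"
    out.loc[out["psi"] < unstable_max, "label"] = "unstable"
    out.loc[out["psi"] > stable_min, "label"] = "stable"
    if inclusive_degron:
        out["is_degron"] = out["psi"] <= degron_cutoff
    else:
        out["is_degron"] = out["psi"] < degron_cutoff
    return out


@dataclass
class DeltaPsiResult:
    """Knockout-vs-control stabilization analysis for one strain."""

    strain: str
    table: pd.DataFrame          # peptide_id, psi_control, psi_ko, delta_psi
    threshold: float             # mean + 2*SE of delta_psi
    stabilized: set = field(default_factory=set)

    @property
    def percent_stabilized(self) -> float:
        return 100.0 * len(self.stabilized) / len(self.table)


def delta_psi_analysis(control: pd.DataFrame,
                       knockouts: dict[str, pd.DataFrame],
                       degron_cutoff: float = DEGRON_CUTOFF,
                       inclusive: bool = True,
                       se_rule: str = "sem") -> dict[str, DeltaPsiResult]:
    """Per-strain stabilization of control degrons by an E3 knockout.

    The analysis is restricted to control-strain degrons (PSI at or below
    ``degron_cutoff``; set ``inclusive=False`` for a strict cutoff) that are
    also scored in the knockout. For each strain, delta-PSI = PSI_ko -
    PSI_control, and the stabilization threshold is mean(delta) + 2*SE
    where SE = sd/sqrt(n) over that strain's delta-PSI values
    (``se_rule="sd"`` substitutes the population sd for the standard error).

    Raises
    ------
    ValueError
        If a strain shares fewer than 3 degrons with the control (the
        standard error is meaningless below that).
    """
    if se_rule not in ("sem", "sd"):
        raise ValueError(f"unknown se_rule {se_rule!r}")
    if inclusive:
        degrons = control.loc[control["psi"] <= degron_cutoff]
    else:
        degrons = control.loc[control["psi"] < degron_cutoff]
    ctrl = degrons.set_index("peptide_id")["psi"]
    results: dict[str, DeltaPsiResult] = {}
    for strain, ko_table in knockouts.items():
        ko = ko_table.set_index("peptide_id")["psi"]
        shared = ctrl.index.intersection(ko.index)
        if len(shared) < 3:
            raise ValueError(
                f"{strain}: only {len(shared)} degrons shared with control"
            )
        delta = (ko.loc[shared] - ctrl.loc[shared]).to_numpy()
        sd = float(np.std(delta, ddof=1))
        se = sd / math.sqrt(len(delta)) if se_rule == "sem" else sd
        threshold = float(np.mean(delta)) + 2.0 * se
        tab = pd.DataFrame({
            "peptide_id": shared,
            "psi_control": ctrl.loc[shared].to_numpy(),
            "psi_ko": ko.loc[shared].to_numpy(),
            "delta_psi": delta,
        })
        stabilized = set(tab.loc[tab["delta_psi"] > threshold, "peptide_id"])
        results[strain] = DeltaPsiResult(
            strain=strain, table=tab, threshold=threshold,
            stabilized=stabilized,
        )
        logger.info("delta_psi[%s]: n=%d threshold=%.4f stabilized=%.1f%%",
                    strain, len(tab), threshold,
                    results[strain].percent_stabilized)
    return results


def e3_overlap(results: dict[str, DeltaPsiResult],
               top_fraction: float = TOP_FRACTION) -> dict:
    """Functional overlap of E3 ligases via their top delta-PSI peptides.

    For each strain, take the ``ceil(top_fraction * n)`` peptides with the
    largest delta-PSI (ties at the boundary broken by peptide id, so the
    selection is deterministic), then report every Venn-region cardinality
    over the strains and the fraction of peptides appearing in the top set
    of at least two strains.
    """
    if len(results) < 2:
        raise ValueError("e3_overlap requires at least 2 strains")
    top_sets: dict[str, set] = {}
    for strain, res in results.items():
        n_top = math.ceil(top_fraction * len(res.table))
        ranked = res.table.sort_values(
            ["delta_psi", "peptide_id"], ascending=[False, True]
        )
        top_sets[strain] = set(ranked["peptide_id"].head(n_top))
    strains = sorted(top_sets)
    universe = set().union(*top_sets.values())
    regions: dict[str, int] = {}
    from itertools import product
    for membership in product([False, True], repeat=len(strains)):
        if not any(membership):
            continue
        region = universe.copy()
        for strain, inside in zip(strains, membership):
            region &= top_sets[strain] if inside else (universe - top_sets[strain])
        key = "&".join(s for s, m in zip(strains, membership) if m)
        regions[key] = len(region)
    in_two_or_more = sum(
        1 for pid in universe
        if sum(pid in s for s in top_sets.values()) >= 2
    )
    return {
        "top_set_sizes": {s: len(top_sets[s]) for s in strains},
        "regions": regions,
        "n_union": len(universe),
        "fraction_multi_e3": in_two_or_more / len(universe) if universe else 0.0,
        "top_sets": top_sets,
    }
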