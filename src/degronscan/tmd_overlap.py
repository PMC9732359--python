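"""Intersection of degron predictions with transmembrane annotations.

Transmembrane domains are strongly hydrophobic, so a composition-based
degron predictor scores most of them as potent degrons. This module
quantifies that relationship: per-residue Venn partitions of predicted
degron residues vs annotated TM residues, classification of TM segments as
high- or low-degron-probability, probability histograms of degron regions
in and out of TMDs, and an amino-acid composition contrast between TM
segment groups.

TM annotations are an input (TMHMM-style interval output or a simple TSV);
the HMM itself is never run here. All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .degron_model import PROB_CUTOFF, DegronProfile
from .seqcore import AMINO_ACIDS, composition

logger = logging.getLogger("degronscan")


class TmFormatError(ValueError):
    pass


@dataclass
class TmAnnotation:
    """Transmembrane segments of one protein (1-based inclusive intervals)."""

    protein_id: str
    segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        segs = sorted(self.segments)
        for (s, e) in segs:
            if e < s or s < 1:
                raise TmFormatError(
                    f"{self.protein_id}: malformed interval ({s}, {e})"
                )
        for (_, e1), (s2, _) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise TmFormatError(
                    f"{self.protein_id}: overlapping TM segments"
                )
        self.segments = segs

    def residue_set(self) -> set[int]:
        out: set[int] = set()
        for s, e in self.segments:
            out.update(range(s, e + 1))
        return out


_PRED_RE = re.compile(r"([a-zA-Z])\s+(\d+)\s+(\d+)")


def parse_tm(path) -> dict[str, TmAnnotation]:
    """Parse TM annotations from TMHMM-style output or interval TSV.

    Two dialects are accepted and detected line by line:

    * TMHMM long format: data lines ``<id> <method> TMhelix <start> <end>``
      (non-TMhelix topology lines are ignored), and posterior ``%pred``
      lines such as ``%pred NB(0): o 1 288, M 289 305, i 306 320`` where
      ``M`` segments are transmembrane; the protein id is taken from the
      preceding ``>`` or ``#`` header.
    * TSV with a ``protein_id  start  end`` header.

    Proteins appearing without any TM line get an empty segment list.
    """
    segments: dict[str, list[tuple[int, int]]] = {}
    current_id: str | None = None
    with open(path) as fh:
        lines = fh.readlines()
    header_tsv = False
    if lines:
        first = lines[0].strip().lower().split("\t")
        header_tsv = first[:3] == ["protein_id", "start", "end"]
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if header_tsv and lineno == 1:
            continue
        if header_tsv:
            parts = line.split("\t")
            if len(parts) < 3:
                raise TmFormatError(f"line {lineno}: expected 3 TSV columns")
            pid, s, e = parts[0], int(parts[1]), int(parts[2])
            if int(e) < int(s):
                raise TmFormatError(
                    f"line {lineno}: end < start ({s}, {e})"
                )
            segments.setdefault(pid, []).append((int(s), int(e)))
            continue
        if line.startswith((">", "#")):
            current_id = line.lstrip(">#").split()[0]
            segments.setdefault(current_id, [])
            continue
        if line.startswith("%pred"):
            if current_id is None:
                raise TmFormatError(
                    f"line {lineno}: %pred line before any protein header"
                )
            body = line.split(":", 1)[1] if ":" in line else line
            for label, s, e in _PRED_RE.findall(body):
                if label == "M":
                    if int(e) < int(s):
                        raise TmFormatError(
                            f"line {lineno}: end < start ({s}, {e})"
                        )
                    segments[current_id].append((int(s), int(e)))
            continue
        parts = line.split()
        if len(parts) >= 5 and parts[2].lower() in ("tmhelix", "tm"):
            s, e = int(parts[3]), int(parts[4])
            if e < s:
                raise TmFormatError(f"line {lineno}: end < start ({s}, {e})")
            segments.setdefault(parts[0], []).append((s, e))
        elif len(parts) >= 5:
            # other topology rows (inside/outside) register the protein
            segments.setdefault(parts[0], [])
    return {
        pid: TmAnnotation(protein_id=pid, segments=segs)
        for pid, segs in segments.items()
    }


def write_tm_tsv(annotations: dict[str, TmAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\n")
        for pid in sorted(annotations):
            for s, e in annotations[pid].segments:
                fh.write(f"{pid}\t{s}\t{e}\n")


def residue_intersection(profiles: dict[str, DegronProfile],
                         annotations: dict[str, TmAnnotation],
                         cutoff: float = PROB_CUTOFF) -> dict:
    """Three-way residue partition: degron-only, TMD-only, both.

    Considered residues are those with a defined degron probability (tile
    centers); a residue is a degron residue when its probability meets the
    cutoff and a TM residue when it lies in an annotated segment. Returns
    residue-level Venn cardinalities plus region/segment-level counts
    (a degron region or TM segment counts as overlapping when they share at
    least one defined residue).
    """
    shared = set(profiles) & set(annotations)
    only_profiles = set(profiles) - shared
    if only_profiles:
        logger.info("residue_intersection: %d proteins lack TM annotation",
                    len(only_profiles))
    degron_only = tmd_only = both = 0
    seg_total = seg_overlap = 0
    region_total = region_overlap = 0
    for pid, prof in profiles.items():
        tm_res = annotations[pid].residue_set() if pid in annotations else set()
        probs = prof.probabilities
        defined = ~np.isnan(probs)
        idx = np.nonzero(defined)[0] + 1          # 1-based residues
        deg_mask = probs[defined] >= cutoff
        deg_res = set(idx[deg_mask])
        tm_defined = tm_res & set(idx)
        both += len(deg_res & tm_defined)
        degron_only += len(deg_res - tm_defined)
        tmd_only += len(tm_defined - deg_res)
        for region in prof.regions:
            region_total += 1
            span = set(range(region["start"], region["end"] + 1))
            if span & tm_res:
                region_overlap += 1
        if pid in annotations:
            for s, e in annotations[pid].segments:
                seg_span = set(range(s, e + 1)) & set(idx)
                if not seg_span:
                    continue
                seg_total += 1
                if seg_span & deg_res:
                    seg_overlap += 1
    return {
        "residues": {
            "degron_only": degron_only,
            "tmd_only": tmd_only,
            "both": both,
            "total_degron": degron_only + both,
            "total_tmd": tmd_only + both,
        },
        "degron_regions": {"total": region_total,
                           "overlapping_tmd": region_overlap},
        "tm_segments": {"total": seg_total,
                        "overlapping_degron": seg_overlap},
    }


def segment_degron_fraction(profiles: dict[str, DegronProfile],
                            annotations: dict[str, TmAnnotation],
                            cutoff: float = PROB_CUTOFF,
                            statistic: str = "max") -> pd.DataFrame:
    """Classify each TM segment as high or low degron probability.

    A segment's summary probability is the maximum (default) or mean of
    the defined per-residue probabilities it spans; segments with no
    defined residue (too close to a terminus) are excluded with a log line.
    Returns a DataFrame: protein_id, start, end, probability, group
    ("high" when probability >= cutoff else "low").
    """
    if statistic not in ("max", "mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rows = []
    excluded = 0
    for pid, ann in annotations.items():
        if pid not in profiles:
            continue
        probs = profiles[pid].probabilities
        for s, e in ann.segments:
            window = probs[s - 1: e]
            window = window[~np.isnan(window)]
            if window.size == 0:
                excluded += 1
                continue
            p = float(window.max() if statistic == "max" else window.mean())
            rows.append({
                "protein_id": pid, "start": s, "end": e,
                "probability": p,
                "group": "high" if p >= cutoff else "low",
            })
    if excluded:
        logger.info("segment_degron_fraction: excluded %d segments with no "
                    "defined probability", excluded)
    return pd.DataFrame(rows,
                        columns=["protein_id", "start", "end",
                                 "probability", "group"])


def probability_bin_distribution(region_probabilities: dict[str, list[float]],
                                 bins: int | np.ndarray = 3,
                                 lo: float = PROB_CUTOFF,
                                 hi: float = 1.0) -> pd.DataFrame:
    """Histogram of degron-region maximum probabilities per group.

    ``region_probabilities`` maps a group name (e.g. "all", "tmd",
    "non_tmd") to its regions' max probabilities. Default 3 equal-width
    bins on [0.85, 1.0]; frequencies are normalized within group and sum
    to 1 for every non-empty group.
    """
    edges = (np.linspace(lo, hi, bins + 1)
             if np.isscalar(bins) else np.asarray(bins, dtype=float))
    out = {}
    for group, values in region_probabilities.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            logger.info("probability_bin_distribution: group %r is empty",
                        group)
            out[group] = np.zeros(len(edges) - 1)
            continue
        hist, _ = np.histogram(np.clip(values, lo, hi), bins=edges)
        out[group] = hist / hist.sum()
    labels = [f"[{edges[i]:.3f},{edges[i+1]:.3f}{']' if i == len(edges)-2 else ')'}"
              for i in range(len(edges) - 1)]
    return pd.DataFrame(out, index=labels)


def composition_contrast(high_sequences, low_sequences) -> dict:
    """Amino-acid composition comparison between two segment groups.

    Reports per-amino-acid mean fractions with normal-approximation 95%
    confidence intervals for each group, an omnibus chi-square test on the
    pooled 2x20 residue count table (df = 19), and a per-amino-acid
    two-sided Mann-Whitney U test on the per-segment fractions.
    """
    high_sequences, low_sequences = list(high_sequences), list(low_sequences)
    if not high_sequences or not low_sequences:
        raise ValueError("both groups must be non-empty")
    if min(len(high_sequences), len(low_sequences)) < 2:
        raise ValueError("Mann-Whitney U needs at least 2 sequences per group")
    high = np.array([composition(s) for s in high_sequences])
    low = np.array([composition(s) for s in low_sequences])

    def group_stats(mat: np.ndarray) -> pd.DataFrame:
        mean = mat.mean(axis=0)
        sem = mat.std(axis=0, ddof=1) / np.sqrt(len(mat))
        return pd.DataFrame({
            "mean": mean, "ci_low": mean - 1.96 * sem,
            "ci_high": mean + 1.96 * sem,
        }, index=list(AMINO_ACIDS))

    # pooled residue counts per group for the omnibus test
    counts_high = np.array([
        sum(s.count(aa) for s in high_sequences) for aa in AMINO_ACIDS
    ])
    counts_low = np.array([
        sum(s.count(aa) for s in low_sequences) for aa in AMINO_ACIDS
    ])
    table = np.vstack([counts_high, counts_low])
    keep = table.sum(axis=0) > 0
    # plain Pearson statistic (no Yates correction, also when df drops to 1)
    chi2, chi2_p, dof, _ = stats.chi2_contingency(table[:, keep],
                                                  correction=False)

    u_tests = {}
    for j, aa in enumerate(AMINO_ACIDS):
        res = stats.mannwhitneyu(high[:, j], low[:, j],
                                 alternative="two-sided")
        u_tests[aa] = {"U": float(res.statistic), "p": float(res.pvalue)}

    return {
        "high": group_stats(high),
        "low": group_stats(low),
        "chi2": float(chi2),
        "chi2_p": float(chi2_p),
        "chi2_dof": int(dof),
        "mannwhitney": u_tests,
    }
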