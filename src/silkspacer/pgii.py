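"""Polyglycine-II (3₁-helix) detection and occurrence statistics.

Standard assignment tools do not recognise the extended three-fold
3₁-helix of polyglycine II, so it is detected directly from backbone
dihedrals: a residue qualifies ("X") when |φ| ∈ [70°, 90°] and
|ψ| ∈ [140°, 150°], and a 3-residue window is 3₁-helical when at least
two of its residues qualify with a common φ sign. Occurrence over an
ensemble is estimated the way it was done on the original trajectories:
a random sample of frames is scored and errors come from bootstrap
resampling of the sampled indicators.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .geometry import compute_dihedrals, detect_hbonds
from .structures import BackboneStructure, ConformerEnsemble

PHI_WINDOW = (70.0, 90.0)    # |phi| bounds, inclusive
PSI_WINDOW = (140.0, 150.0)  # |psi| bounds, inclusive


def residue_qualifies(phi: float, psi: float) -> bool:
    """True when (phi, psi) lies in the 3₁ dihedral window (either hand)."""
    if not (np.isfinite(phi) and np.isfinite(psi)):
        return False
    return (
        PHI_WINDOW[0] <= abs(phi) <= PHI_WINDOW[1]
        and PSI_WINDOW[0] <= abs(psi) <= PSI_WINDOW[1]
    )


@dataclass
class PGIISegment:
    """A maximal run of overlapping qualifying 3-residue windows."""

    chain: int
    start_resnum: int
    length: int
    qualifying: np.ndarray   # bool mask over the segment (X vs Y positions)
    handedness: str          # "right" for negative phi, "left" for positive

    @property
    def patterns(self) -> list[str]:
        """Window patterns over the segment: "XX" (adjacent) or "XYX"."""
        out = []
        q = self.qualifying
        for i in range(len(q) - 2):
            w = q[i:i + 3]
            if w.sum() < 2:
                continue
            out.append("XYX" if (w[0] and w[2] and not w[1]) else "XX")
        return out


def _window_qualifies(phis: np.ndarray, psis: np.ndarray) -> tuple[bool, int]:
    """Evaluate one 3-residue window; returns (qualifies, phi-sign of X residues)."""
    q = [residue_qualifies(p, s) for p, s in zip(phis, psis)]
    for sign in (-1, 1):
        hits = [qi and np.sign(p) == sign for qi, p in zip(q, phis)]
        if sum(hits) >= 2:
            return True, sign
    return False, 0


def detect_pgii(
    dihedrals: np.ndarray, chain: int = 0, first_resnum: int = 1
) -> list[PGIISegment]:
    """Detect 3₁-helical segments in one chain's (n, 3) dihedral series.

    Slides a 3-residue window; a window qualifies when ≥ 2 residues have
    |φ| ∈ [70, 90] and |ψ| ∈ [140, 150] (inclusive) with a common φ
    sign. Overlapping qualifying windows of one handedness merge into
    maximal segments.
    """
    dihedrals = np.asarray(dihedrals, dtype=float)
    n = len(dihedrals)
    if n < 3:
        return []
    window_hits = []  # (start, sign)
    for i in range(n - 2):
        ok, sign = _window_qualifies(dihedrals[i:i + 3, 0], dihedrals[i:i + 3, 1])
        if ok:
            window_hits.append((i, sign))
    segments: list[PGIISegment] = []
    k = 0
    while k < len(window_hits):
        start, sign = window_hits[k]
        end = start + 2
        k += 1
        while k < len(window_hits) and window_hits[k][0] <= end and window_hits[k][1] == sign:
            end = window_hits[k][0] + 2
            k += 1
        mask = np.array([
            residue_qualifies(dihedrals[j, 0], dihedrals[j, 1])
            and np.sign(dihedrals[j, 0]) == sign
            for j in range(start, end + 1)
        ])
        segments.append(PGIISegment(
            chain=chain,
            start_resnum=first_resnum + start,
            length=end - start + 1,
            qualifying=mask,
            handedness="right" if sign < 0 else "left",
        ))
    return segments


def detect_pgii_frame(structure: BackboneStructure) -> list[PGIISegment]:
    """PGII segments over all chains of one frame."""
    segments = []
    for c, (chain, dih) in enumerate(
        zip(structure.chains, compute_dihedrals(structure))
    ):
        segments.extend(detect_pgii(dih, chain=c, first_resnum=int(chain.resnums[0])))
    return segments


# ---------------------------------------------------------------------------
# Sampled occurrence with bootstrap errors
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceEstimate:
    """Sampled-frame occurrence of 3₁-helices with bootstrap uncertainty."""

    fraction_frames: float        # fraction of sampled frames with >= 1 segment
    segments_per_frame: float     # mean segment count over sampled frames
    bootstrap_mean: float
    ci_low: float
    ci_high: float
    n_sampled: int
    n_bootstrap: int
    seed: int | None


def estimate_occurrence(
    ensemble: ConformerEnsemble,
    n_samples: int = 400,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    detector=detect_pgii_frame,
) -> OccurrenceEstimate:
    """Estimate 3₁-helix occurrence from a random sample of frames.

    Frames are drawn uniformly (without replacement while the sample
    fits, with replacement otherwise); the point estimate is the
    fraction of sampled frames containing at least one segment, and the
    95% CI comes from percentile bootstrap over the sampled indicators.
    """
    if ensemble.n_frames < 1:
        raise InputError("empty ensemble")
    if n_bootstrap < 1:
        raise InputError("n_bootstrap must be >= 1")
    rng = np.random.default_rng(seed)
    if n_samples <= ensemble.n_frames:
        idx = rng.choice(ensemble.n_frames, size=n_samples, replace=False)
    else:
        idx = rng.choice(ensemble.n_frames, size=n_samples, replace=True)
    counts = np.array([len(detector(ensemble.frames[i])) for i in idx])
    indicators = (counts > 0).astype(float)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        resample = rng.choice(n_samples, size=n_samples, replace=True)
        boot[b] = indicators[resample].mean()
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return OccurrenceEstimate(
        fraction_frames=float(indicators.mean()),
        segments_per_frame=float(counts.mean()),
        bootstrap_mean=float(boot.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_sampled=n_samples,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Sequence composition of helices
# ---------------------------------------------------------------------------

@dataclass
class CompositionTable:
    """Amino-acid composition of 3₁ windows and 3₁₀ helices.

    ``pgii`` maps pattern ("XX" / "XYX") -> {residue: (percent, err)};
    ``g310`` maps subset ("overall" / "left" / "right") -> {residue: percent};
    ``hbond_mean`` / ``hbond_sd`` summarise i→i+3 H···O lengths within
    3₁₀ segments.
    """

    pgii: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    g310: dict[str, dict[str, float]] = field(default_factory=dict)
    hbond_mean: float = float("nan")
    hbond_sd: float = float("nan")
    n_hbonds: int = 0


def _percentages(counter: Counter) -> dict[str, float]:
    total = sum(counter.values())
    if total == 0:
        return {}
    return {aa: 100.0 * c / total for aa, c in sorted(counter.items())}


def composition_stats(
    ensemble: ConformerEnsemble,
    assignments=None,
    pgii_segments: list[list[PGIISegment]] | None = None,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> CompositionTable:
    """Sequence composition of 3₁ windows and 3₁₀ helices over an ensemble.

    3₁ side: qualifying (X) residues are tallied separately for windows
    whose X residues are adjacent (XX) and separated (XYX); errors are
    bootstrap standard deviations over frames. 3₁₀ side: amino-acid
    occurrence among G-labelled residues, overall and by segment
    handedness, plus the mean ± sd of i→i+3 H···O bond lengths inside G
    segments.
    """
    from .assign import assign_ensemble

    rng = np.random.default_rng(seed)
    if pgii_segments is None:
        pgii_segments = [detect_pgii_frame(f) for f in ensemble.frames]
    if assignments is None:
        assignments = assign_ensemble(ensemble)

    # --- 3₁ composition per frame (for bootstrap errors) -------------------
    per_frame: list[dict[str, Counter]] = []
    for frame, segments in zip(ensemble.frames, pgii_segments):
        tallies = {"XX": Counter(), "XYX": Counter()}
        for seg in segments:
            chain = frame.chains[seg.chain]
            offset = seg.start_resnum - int(chain.resnums[0])
            q = seg.qualifying
            for i in range(len(q) - 2):
                w = q[i:i + 3]
                if w.sum() < 2:
                    continue
                pattern = "XYX" if (w[0] and w[2] and not w[1]) else "XX"
                for j in range(3):
                    if w[j]:
                        aa = chain.sequence[offset + i + j]
                        tallies[pattern][aa] += 1
        per_frame.append(tallies)

    table = CompositionTable()
    for pattern in ("XX", "XYX"):
        pooled = Counter()
        for t in per_frame:
            pooled.update(t[pattern])
        point = _percentages(pooled)
        boots: dict[str, list[float]] = {aa: [] for aa in point}
        nf = len(per_frame)
        for _ in range(n_bootstrap):
            resample = rng.choice(nf, size=nf, replace=True)
            agg = Counter()
            for fi in resample:
                agg.update(per_frame[fi][pattern])
            pct = _percentages(agg)
            for aa in boots:
                boots[aa].append(pct.get(aa, 0.0))
        table.pgii[pattern] = {
            aa: (point[aa], float(np.std(boots[aa])) if boots[aa] else 0.0)
            for aa in point
        }

    # --- 3₁₀ composition and H-bond lengths --------------------------------
    tallies = {"overall": Counter(), "left": Counter(), "right": Counter()}
    ho_lengths: list[float] = []
    for frame, assignment in zip(ensemble.frames, assignments):
        bonds = detect_hbonds(frame)
        bond_lookup = {
            (b.donor[0], b.donor[1]): b
            for b in bonds
            if b.pattern_offset == 3
        }
        for seg in assignment.g_segments:
            chain = frame.chains[seg.chain]
            offset = seg.start_resnum - int(chain.resnums[0])
            for j in range(seg.length):
                aa = chain.sequence[offset + j]
                tallies["overall"][aa] += 1
                if not seg.ambiguous:
                    tallies[seg.handedness][aa] += 1
            # i→i+3 bonds whose donor lies in (or just past) the segment
            for rn in range(seg.start_resnum, seg.start_resnum + seg.length + 1):
                b = bond_lookup.get((seg.chain, rn))
                if b is not None and b.acceptor[1] >= seg.start_resnum - 1:
                    ho_lengths.append(b.h_o_distance)
    for subset, counter in tallies.items():
        table.g310[subset] = _percentages(counter)
    if ho_lengths:
        arr = np.asarray(ho_lengths)
        table.hbond_mean = float(arr.mean())
        table.hbond_sd = float(arr.std())
        table.n_hbonds = len(ho_lengths)
    return table
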