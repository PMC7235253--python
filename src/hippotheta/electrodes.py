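"""Anatomical normalization and single/dual oscillator classification.

Electrode position along the hippocampal anterior-posterior (A-P) axis is
normalized between the first and last MRI slice containing the hippocampus
(0 = anterior tip, 1 = posterior tip), split into anterior/posterior at the
0.40 fraction.  An electrode is a *dual oscillator* when it carries two
detected bands whose nearest edges differ by at least 0.5 Hz; otherwise its
bands are merged and it is a *single oscillator*.  Bands are labeled low
theta (peak < 4 Hz) or high theta (peak >= 4 Hz).  Redundant neighboring
contacts (within 10% of the A-P axis and with a band peak within 2 Hz) are
deduplicated, keeping the lowest electrode id.
"""

from __future__ import annotations

from hippotheta.types import Band, ElectrodeRecord

__all__ = [
    "normalize_ap",
    "split_region",
    "classify_oscillator",
    "band_label",
    "deduplicate",
    "classify_records",
]

AP_CUT = 0.40
EDGE_GAP_HZ = 0.5
LOW_HIGH_SPLIT_HZ = 4.0
DEDUP_AP_RADIUS = 0.10
DEDUP_FREQ_HZ = 2.0


def normalize_ap(slice_index: float, first_slice: float, last_slice: float) -> float:
    """Normalized A-P fraction of an MRI slice index."""
    if not first_slice < last_slice:
        raise ValueError("first_slice must be < last_slice")
    if not first_slice <= slice_index <= last_slice:
        raise ValueError("slice_index outside [first_slice, last_slice]")
    return (slice_index - first_slice) / (last_slice - first_slice)


def split_region(ap_fraction: float, cut: float = AP_CUT) -> str:
    """'posterior' iff ap_fraction >= cut (boundary assigned posterior)."""
    if not 0.0 <= ap_fraction <= 1.0:
        raise ValueError("ap_fraction must be in [0, 1]")
    return "posterior" if ap_fraction >= cut else "anterior"


def band_label(band: Band, split_hz: float = LOW_HIGH_SPLIT_HZ) -> str:
    """'low' for peak below 4 Hz, 'high' for peak at or above 4 Hz."""
    return "low" if band.peak_freq < split_hz else "high"


def classify_oscillator(bands: list[Band],
                        edge_gap_hz: float = EDGE_GAP_HZ
                        ) -> tuple[str, list[Band], list[str]]:
    """Classify a detected band set as single or dual oscillator.

    Two bands whose nearest edges differ by at least ``edge_gap_hz`` make a
    dual oscillator.  Bands closer than that are merged into the span of
    their union (single oscillator, peak taken from the stronger definition:
    the original band peaks' extreme closest to the merged span is kept via
    the first band's peak — by convention the peak of the merged band is the
    peak of the band whose edges the merge started from).  More than two
    well-separated bands are reduced to the two with the widest spans.
    Raises on an empty band list (such electrodes are flagged upstream).
    """
    if not bands:
        raise ValueError("electrode has no detected bands in 2-14 Hz")
    ordered = sorted(bands, key=lambda b: b.f_lo)
    merged: list[Band] = [ordered[0]]
    for b in ordered[1:]:
        prev = merged[-1]
        if b.f_lo - prev.f_hi < edge_gap_hz:
            f_lo, f_hi = prev.f_lo, max(prev.f_hi, b.f_hi)
            peak = prev.peak_freq if prev.f_hi - prev.f_lo >= b.f_hi - b.f_lo else b.peak_freq
            merged[-1] = Band(f_lo=f_lo, f_hi=f_hi, peak_freq=peak)
        else:
            merged.append(b)
    if len(merged) > 2:
        merged = sorted(
            sorted(merged, key=lambda b: b.f_hi - b.f_lo, reverse=True)[:2],
            key=lambda b: b.f_lo,
        )
    osc_class = "dual" if len(merged) == 2 else "single"
    labels = [band_label(b) for b in merged]
    return osc_class, merged, labels


def classify_records(records: list[ElectrodeRecord],
                     detected: dict[str, list[Band]]) -> list[ElectrodeRecord]:
    """Apply region split and oscillator classification to a cohort in place.

    Electrodes with no detected band are flagged ``excluded`` rather than
    classified.
    """
    for rec in records:
        rec.region = split_region(rec.ap_fraction)
        bands = detected.get(rec.electrode_id, [])
        if not bands:
            rec.excluded = True
            rec.bands = []
            rec.oscillator_class = None
            rec.band_labels = []
            continue
        osc_class, merged, labels = classify_oscillator(bands)
        rec.oscillator_class = osc_class
        rec.bands = merged
        rec.band_labels = labels
    return records


def deduplicate(records: list[ElectrodeRecord],
                ap_radius: float = DEDUP_AP_RADIUS,
                freq_tol_hz: float = DEDUP_FREQ_HZ) -> list[ElectrodeRecord]:
    """Drop redundant neighboring contacts, keeping the lowest electrode id.

    Within each (subject, hemisphere) group, electrodes closer than
    ``ap_radius`` along the A-P axis whose band peak frequencies agree within
    ``freq_tol_hz`` (any band pair, for dual oscillators) are treated as one
    contact; redundancy is applied transitively (connected components).
    """
    kept: list[ElectrodeRecord] = []
    groups: dict[tuple[str, str], list[ElectrodeRecord]] = {}
    for r in records:
        groups.setdefault((r.subject_id, r.hemisphere), []).append(r)
    for group in groups.values():
        n = len(group)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = group[i], group[j]
                if a.excluded or b.excluded:
                    continue
                if abs(a.ap_fraction - b.ap_fraction) >= ap_radius:
                    continue
                close = any(
                    abs(ba.peak_freq - bb.peak_freq) <= freq_tol_hz
                    for ba in a.bands
                    for bb in b.bands
                )
                if close:
                    parent[find(i)] = find(j)
        comps: dict[int, list[ElectrodeRecord]] = {}
        for i, r in enumerate(group):
            comps.setdefault(find(i), []).append(r)
        for members in comps.values():
            kept.append(min(members, key=lambda r: r.electrode_id))
    kept.sort(key=lambda r: (r.subject_id, r.electrode_id))
    return kept
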