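"""Small summary-reporting helpers shared by Results.summary() and the CLI."""

from __future__ import annotations


def fraction_pct(part: float, whole: float, ndigits: int | None = None) -> float:
    """``part / whole`` expressed in percent; optionally rounded.

    This single division is the code path behind every percentage the
    summaries print (DMC rates, overlap shares, target fractions).
    """
    if whole == 0:
        raise ZeroDivisionError("cannot express a fraction of an empty total")
    pct = 100.0 * part / whole
    return pct if ndigits is None else round(pct, ndigits)


def count_summary_lines(counts: dict[str, int], total: float | None = None) -> list[str]:
    """Human-readable 'label: n (x.x%)' lines for a count table."""
    lines = []
    for label, n in counts.items():
        if total:
            lines.append(f"{label}: {n} ({fraction_pct(n, total, 1)}%)")
        else:
            lines.append(f"{label}: {n}")
    return lines
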