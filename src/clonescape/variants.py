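"""Tumor mutational burden, substitution spectrum, and subclone sharing."""

from __future__ import annotations

import warnings

import pandas as pd

from .io import VariantSet

__all__ = [
    "SPECTRUM_CLASSES",
    "compute_tmb",
    "substitution_spectrum",
    "partition_sharing",
]

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def classify_substitution(ref: str, alt: str) -> str | None:
    """Pyrimidine-centric class of a single-base substitution.

    Purine-reference records collapse by reverse complement (G>A -> C>T);
    indels and ambiguous bases return None.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        return None
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        return None
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def compute_tmb(v: VariantSet, level: str | None = None) -> pd.DataFrame:
    """Deduplicated variant count / genome megabases per (sample, level).

    ``level`` restricts to one level tag ("bulk", "subclone:<id>" or the
    prefix "subclone" for all subclone levels); None keeps everything.
    """
    rows = []
    seen: dict[tuple, set] = {}
    for r in v.records:
        if level is not None:
            if level == "subclone":
                if not r.level.startswith("subclone:"):
                    continue
            elif r.level != level:
                continue
        seen.setdefault((r.sample, r.level), set()).add(r.key())
    for (sample, lvl), keys in sorted(seen.items()):
        n = len(keys)
        rows.append(
            {"sample": sample, "level": lvl, "n_variants": n,
             "tmb": n / v.genome_size_mb}
        )
    return pd.DataFrame(rows, columns=["sample", "level", "n_variants", "tmb"])


def substitution_spectrum(v: VariantSet) -> pd.DataFrame:
    """Six-class substitution counts and fractions per (sample, level).

    Indels are excluded from the classes but reported in ``n_excluded``;
    ambiguous bases raise a warning.
    """
    buckets: dict[tuple, dict] = {}
    n_ambiguous = 0
    for r in v.records:
        key = (r.sample, r.level)
        b = buckets.setdefault(key, {c: 0 for c in SPECTRUM_CLASSES} | {"n_excluded": 0})
        cls = classify_substitution(r.ref, r.alt)
        if cls is None:
            if len(r.ref) == 1 and len(r.alt) == 1:
                n_ambiguous += 1
            b["n_excluded"] += 1
        else:
            b[cls] += 1
    if n_ambiguous:
        warnings.warn(f"excluded {n_ambiguous} records with ambiguous bases")
    rows = []
    for (sample, lvl), b in sorted(buckets.items()):
        total = sum(b[c] for c in SPECTRUM_CLASSES)
        row = {"sample": sample, "level": lvl, "n_snv": total,
               "n_excluded": b["n_excluded"]}
        for c in SPECTRUM_CLASSES:
            row[f"count_{c}"] = b[c]
            row[f"frac_{c}"] = b[c] / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def partition_sharing(v: VariantSet, sample: str) -> dict:
    """Split one sample's subclone variants into shared vs restricted.

    ``shared``: keys present in every subclone; ``restricted``: map
    subclone -> keys it carries that are not shared; ``presence``:
    variant x subclone boolean DataFrame.
    """
    subclones = v.subclones(sample)
    if len(subclones) < 2:
        raise ValueError(f"sample {sample!r} has fewer than 2 subclone levels")
    per_sub = {
        s: {
            r.key()
            for r in v.records
            if r.sample == sample and r.level == f"subclone:{s}"
        }
        for s in subclones
    }
    all_keys = sorted(set().union(*per_sub.values()))
    shared = set.intersection(*per_sub.values()) if all_keys else set()
    restricted = {s: per_sub[s] - shared for s in subclones}
    presence = pd.DataFrame(
        {s: [k in per_sub[s] for k in all_keys] for s in subclones},
        index=pd.Index(
            [f"{c}:{p}:{ref}>{alt}" for c, p, ref, alt in all_keys], name="variant"
        ),
    )
    return {"shared": shared, "restricted": restricted, "presence": presence}
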