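"""Downstream screening of enamel-proteome peptide-spectrum matches.

Consumes PSM tables from an upstream database search (one row per spectrum
with the matched peptide, parent protein, 1-based start position,
modifications and per-site fragmentation-support flags) and computes:

* diagenesis-related PTM rates by relative spectral counting — the number
  of PSMs carrying a given PTM on a modifiable residue divided by the
  number of PSMs containing at least one such residue;
* position-wise residue counts around phosphorylated serines and the
  fraction matching the S-x-E motif (glutamate two residues downstream);
* coverage of lineage-diagnostic amino-acid sites and the most exclusive
  taxon call consistent with all fragmentation-supported observations;
* presence/absence screening of AMELY-specific peptides (isoleucine and
  leucine treated as equivalent), with the conservative sex inference:
  absence of AMELY never yields a bare "female" call.

Blank-run PSMs are excluded from every statistic.  Proteins supported by a
single distinct peptide, and proteins on a caller-supplied contaminant
list, are removed before analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .core import ValidationError

__all__ = [
    "PSM", "SitePanel", "PtmRate", "read_psm_tsv", "filter_psms", "ptm_rate",
    "phospho_motif", "diagnostic_coverage", "amely_screen", "normalize_il",
]

PHOSPHO = "Phospho"
DEAMIDATION = "Deamidation"


@dataclass
class PSM:
    """One peptide-spectrum match."""

    peptide: str
    protein: str
    start: int = 1                    # 1-based position in the protein
    mods: list[tuple[int, str]] = field(default_factory=list)
    site_support: dict[int, bool] = field(default_factory=dict)
    is_blank: bool = False
    score: float | None = None        # accepted but unused by default

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError("start must be >= 1")
        for pos, _name in self.mods:
            if not 1 <= pos <= len(self.peptide):
                raise ValidationError(
                    f"modification position {pos} outside peptide "
                    f"{self.peptide!r}")

    def residue_at(self, protein_pos: int) -> str | None:
        """Residue observed at a 1-based protein position, or None if the
        peptide does not span it."""
        offset = protein_pos - self.start
        if 0 <= offset < len(self.peptide):
            return self.peptide[offset]
        return None

    def supported_at(self, protein_pos: int) -> bool:
        offset = protein_pos - self.start + 1      # 1-based in peptide
        return bool(self.site_support.get(offset, False))


@dataclass
class SitePanel:
    """Lineage-diagnostic amino-acid positions.

    ``entries`` maps (protein, 1-based position) to {lineage: residue}.
    """

    entries: dict[tuple[str, int], dict[str, str]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("site panel is empty")
        for (prot, pos), mapping in self.entries.items():
            if pos < 1:
                raise ValidationError(f"{prot}:{pos}: positions are 1-based")
            for lineage, res in mapping.items():
                if len(res) != 1 or not res.isalpha():
                    raise ValidationError(
                        f"{prot}:{pos}: residue for {lineage!r} must be a "
                        "single amino-acid code")

    @property
    def lineages(self) -> set[str]:
        out: set[str] = set()
        for mapping in self.entries.values():
            out.update(mapping)
        return out


def normalize_il(seq: str) -> str:
    """Collapse the mass-indistinguishable isoleucine/leucine pair."""
    return seq.upper().replace("I", "L")


# ---------------------------------------------------------------------------
# table handling

def read_psm_tsv(path) -> list[PSM]:
    """Read a PSM table from TSV.

    Columns: peptide, protein, start, modifications ("pos:Name;..."),
    site_support ("pos:0|1;..."), is_blank; an optional score column is
    carried along.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["peptide", "protein", "start"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns in {path}: {missing}")
    out = []
    for _, row in df.iterrows():
        mods = []
        raw = row.get("modifications")
        if isinstance(raw, str) and raw.strip():
            for item in raw.split(";"):
                pos, name = item.split(":", 1)
                mods.append((int(pos), name.strip()))
        support: dict[int, bool] = {}
        raw = row.get("site_support")
        if isinstance(raw, str) and raw.strip():
            for item in raw.split(";"):
                pos, flag = item.split(":", 1)
                support[int(pos)] = flag.strip() in ("1", "true", "True")
        out.append(PSM(
            peptide=str(row["peptide"]).strip(),
            protein=str(row["protein"]).strip(),
            start=int(row["start"]), mods=mods, site_support=support,
            is_blank=bool(row.get("is_blank", False)),
            score=float(row["score"]) if "score" in df.columns
            and pd.notna(row.get("score")) else None))
    return out


def filter_psms(table: list[PSM], contaminants: set[str] | None = None,
                min_distinct_peptides: int = 2,
                drop_blanks: bool = True) -> list[PSM]:
    """Remove blank-run PSMs, contaminant proteins and proteins supported
    by fewer than ``min_distinct_peptides`` distinct peptides."""
    contaminants = contaminants or set()
    working = [p for p in table if not (drop_blanks and p.is_blank)]
    peptides_per_protein: dict[str, set[str]] = {}
    for p in working:
        peptides_per_protein.setdefault(p.protein, set()).add(
            normalize_il(p.peptide))
    keep_proteins = {prot for prot, peps in peptides_per_protein.items()
                     if len(peps) >= min_distinct_peptides
                     and prot not in contaminants}
    return [p for p in working if p.protein in keep_proteins]


# ---------------------------------------------------------------------------
# PTM spectral counting

@dataclass
class PtmRate:
    """Relative spectral count of one PTM: PSMs carrying the PTM on a
    target residue / PSMs containing at least one target residue."""

    ptm: str
    target_residues: str
    n_modified: int
    n_with_residue: int

    @property
    def undefined(self) -> bool:
        return self.n_with_residue == 0

    @property
    def pct(self) -> float | None:
        if self.undefined:
            return None
        return 100.0 * self.n_modified / self.n_with_residue


def ptm_rate(table: list[PSM], ptm: str, target_residues) -> PtmRate:
    """Relative spectral count of ``ptm`` over ``target_residues``.

    Blank-run PSMs are excluded.  A PSM counts as modified when it carries
    ``ptm`` at a position holding one of the target residues.
    """
    targets = set(target_residues)
    working = [p for p in table if not p.is_blank]
    if not working:
        raise ValidationError("no PSMs left after blank exclusion")
    n_with = 0
    n_mod = 0
    for p in working:
        if not targets.intersection(p.peptide):
            continue
        n_with += 1
        if any(name == ptm and p.peptide[pos - 1] in targets
               for pos, name in p.mods):
            n_mod += 1
    return PtmRate(ptm=ptm, target_residues="".join(sorted(targets)),
                   n_modified=n_mod, n_with_residue=n_with)


def phospho_motif(table: list[PSM], offsets=range(-5, 6)) -> dict:
    """Sequence context of phosphorylated serines.

    Returns a residue-by-offset count table (logo-style) over the given
    offsets and the S-x-E fraction: phospho-S sites with glutamate at +2
    divided by phospho-S sites whose +2 position lies within the peptide.
    """
    counts: dict[int, dict[str, int]] = {o: {} for o in offsets}
    n_sxe = 0
    n_defined = 0
    n_sites = 0
    for p in table:
        if p.is_blank:
            continue
        for pos, name in p.mods:
            if name != PHOSPHO or p.peptide[pos - 1] != "S":
                continue
            n_sites += 1
            for o in offsets:
                j = pos - 1 + o
                if 0 <= j < len(p.peptide):
                    res = p.peptide[j]
                    counts[o][res] = counts[o].get(res, 0) + 1
            j2 = pos + 1              # offset +2, 0-based
            if j2 < len(p.peptide):
                n_defined += 1
                if p.peptide[j2] == "E":
                    n_sxe += 1
    if n_sites == 0:
        raise ValidationError("no phosphorylated serine PSMs in the table")
    table_df = pd.DataFrame(counts).fillna(0).astype(int)
    table_df.index.name = "residue"
    return {"counts": table_df, "n_phospho_s": n_sites,
            "sxe_fraction": (n_sxe / n_defined) if n_defined else None,
            "n_sxe_defined": n_defined}


# ---------------------------------------------------------------------------
# diagnostic sites and sex screening

def diagnostic_coverage(table: list[PSM], panel: SitePanel,
                        homo_lineages: set[str] | None = None) -> dict:
    """Per-site coverage report and the most exclusive taxon call.

    A site counts as *resolved* only when at least one non-blank PSM spans
    it with fragmentation support and all supported observations agree
    (conflicting sites are flagged and excluded from the call).  The call
    intersects, over resolved sites, the lineages whose expected residue
    matches the observation (I/L-equivalent).
    """
    if homo_lineages is None:
        homo_lineages = {ln for ln in panel.lineages
                         if not ln.lower().startswith(("pan", "gorilla",
                                                       "pongo", "ape"))}
    sites = []
    compatible = set(panel.lineages)
    for (prot, pos), mapping in sorted(panel.entries.items()):
        observations = []
        covered = False
        supported = False
        for p in table:
            if p.is_blank or p.protein != prot:
                continue
            res = p.residue_at(pos)
            if res is None:
                continue
            covered = True
            if p.supported_at(pos):
                supported = True
                observations.append(normalize_il(res))
        obs_set = set(observations)
        conflict = len(obs_set) > 1
        entry = {"protein": prot, "position": pos, "covered": covered,
                 "supported": supported, "conflict": conflict,
                 "observed": sorted(obs_set),
                 "expected": dict(mapping)}
        if supported and not conflict:
            obs = observations[0]
            matching = {ln for ln, res in mapping.items()
                        if normalize_il(res) == obs}
            entry["compatible_lineages"] = sorted(matching)
            compatible &= matching
        sites.append(entry)

    resolved = [s for s in sites if s["supported"] and not s["conflict"]]
    outgroups = panel.lineages - homo_lineages
    if not resolved:
        call = "indeterminate (no diagnostic site resolved)"
    elif compatible == set():
        call = "no lineage consistent with all resolved sites"
    elif homo_lineages <= compatible and not (compatible & outgroups):
        call = "genus Homo; within-Homo indeterminate"
    elif compatible < homo_lineages:
        call = "consistent with: " + ", ".join(sorted(compatible))
    else:
        call = "indeterminate"
    return {"sites": sites, "compatible_lineages": sorted(compatible),
            "call": call, "n_resolved": len(resolved)}


def amely_screen(table: list[PSM], amely_specific_peptides) -> dict:
    """Screen for male-diagnostic amelogenin-Y peptides.

    A PSM matches when, after I/L normalisation, its sequence contains or
    is contained in an AMELY-specific reference peptide.  Detection infers
    "male"; absence infers "female or degraded beyond detection" — never a
    bare "female", since AMELY peptides can simply have been lost.
    """
    refs = [normalize_il(s) for s in amely_specific_peptides]
    if not refs:
        raise ValidationError("AMELY-specific reference set is empty")
    hits = []
    for p in table:
        if p.is_blank:
            continue
        seq = normalize_il(p.peptide)
        if any(ref in seq or seq in ref for ref in refs):
            hits.append(p.peptide)
    detected = bool(hits)
    return {"amely_detected": detected,
            "matching_peptides": hits,
            "inference": "male" if detected
            else "female or degraded beyond detection"}


def screening_report(table: list[PSM], panel: SitePanel | None,
                     amely_peptides, ptms: dict[str, str] | None = None,
                     contaminants: set[str] | None = None) -> dict:
    """One-call screening: filtering, PTM rates, motif, sites, AMELY."""
    filtered = filter_psms(table, contaminants=contaminants)
    ptms = ptms or {PHOSPHO: "STY", DEAMIDATION: "NQ",
                    "Oxidation": "MW", "Hydroxyproline": "P"}
    rates = {}
    for name, residues in ptms.items():
        r = ptm_rate(filtered, name, residues)
        rates[name] = {"pct": r.pct, "n_modified": r.n_modified,
                       "n_with_residue": r.n_with_residue}
    try:
        motif = phospho_motif(filtered)
        motif_out = {"sxe_fraction": motif["sxe_fraction"],
                     "n_phospho_s": motif["n_phospho_s"]}
    except ValidationError:
        motif_out = None
    report = {"n_psm_input": len(table), "n_psm_after_filter": len(filtered),
              "ptm_rates": rates, "phospho_motif": motif_out,
              "amely": amely_screen(filtered, amely_peptides)}
    if panel is not None:
        cov = diagnostic_coverage(filtered, panel)
        report["diagnostic_sites"] = {"call": cov["call"],
                                      "n_resolved": cov["n_resolved"],
                                      "compatible_lineages":
                                          cov["compatible_lineages"]}
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
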