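"""End-to-end allele comparison: the orchestration layer behind the CLI.

``compare_alleles`` runs the whole analysis between a wild-type and a
mutant conformational ensemble: time-averaging, the distance-difference
map with its domain block summary, interface-pair discovery on the
wild-type average with per-pair separation changes, per-residue
displacement (key residues highlighted), relative-solvent-accessibility
changes, and a hydrogen-bond presence/absence diff.  Every stage is a
plain library call — the bundle it returns contains nothing a caller could
not compute directly from the modules.
"""

from __future__ import annotations

import dataclasses
import json
import time
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .contacts import (ContactCriteria, DomainSpec, HBondCriteria,
                       diff_block_summary, distance_diff_map, find_hbonds,
                       find_interface_pairs, hbond_table,
                       interface_pair_table, pair_distance_report)
from .geometry import displacement_table, per_residue_displacement, time_average
from .mapping import ResidueMap, map_from_duplication
from .pdbio import Ensemble, Structure
from .sasa import SASAParams, residue_rsa, rsa_delta, rsa_table
from .similarity import ClusterCriteria

__all__ = ["AnalysisConfig", "compare_alleles", "write_reports"]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the comparison pipeline.

    Defaults carry the AKT1 conventions: PH domain residues 5-108, kinase
    domain 150-408, and the named key residues (E17, N53, Q79, T308, D323,
    S473).  ``superposition_frame`` chooses the rigid reference for
    displacement: the domain the perturbation is expected not to move
    ("domain_b" = kinase by default; "domain_a" or "all" otherwise).
    """

    domain_a: DomainSpec = field(default_factory=lambda: DomainSpec("PH", [(5, 108)]))
    domain_b: DomainSpec = field(default_factory=lambda: DomainSpec("kinase", [(150, 408)]))
    contact: ContactCriteria = field(default_factory=ContactCriteria)
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    sasa: SASAParams = field(default_factory=SASAParams)
    cluster: ClusterCriteria = field(default_factory=ClusterCriteria)
    key_residues: tuple[int, ...] = (17, 53, 79, 308, 323, 473)
    superposition_frame: str = "domain_b"  # domain_a | domain_b | all
    diff_metric: str = "ca"
    displacement_representative: str = "CA"
    alpha: float = 0.05
    seed: int = 0

    def frame_residues(self) -> list[int] | None:
        if self.superposition_frame == "domain_a":
            return [r for lo, hi in self.domain_a.ranges for r in range(lo, hi + 1)]
        if self.superposition_frame == "domain_b":
            return [r for lo, hi in self.domain_b.ranges for r in range(lo, hi + 1)]
        return None

    # -- JSON round-trip ------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def enc(v):
            if isinstance(v, DomainSpec):
                return {"name": v.name, "ranges": [list(r) for r in v.ranges]}
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {f.name: enc(getattr(v, f.name))
                        for f in dataclasses.fields(v)}
            if isinstance(v, frozenset):
                return sorted(v)
            if isinstance(v, tuple):
                return list(v)
            if isinstance(v, dict):
                return dict(v)
            return v
        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "AnalysisConfig":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            v = data[f.name]
            if f.name in ("domain_a", "domain_b"):
                kwargs[f.name] = DomainSpec(v["name"], v["ranges"])
            elif f.name == "contact":
                v = dict(v)
                if "hydrophobic_residues" in v:
                    v["hydrophobic_residues"] = frozenset(v["hydrophobic_residues"])
                kwargs[f.name] = ContactCriteria(**v)
            elif f.name == "hbond":
                v = dict(v)
                if "donor_acceptor_elements" in v:
                    v["donor_acceptor_elements"] = frozenset(v["donor_acceptor_elements"])
                kwargs[f.name] = HBondCriteria(**v)
            elif f.name == "sasa":
                kwargs[f.name] = SASAParams(**v)
            elif f.name == "cluster":
                kwargs[f.name] = ClusterCriteria(**v)
            elif f.name == "key_residues":
                kwargs[f.name] = tuple(v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisConfig":
        if isinstance(source, Path) or Path(str(source)).is_file():
            text = Path(source).read_text()
        else:
            text = str(source)
        return cls.from_dict(json.loads(text))


def _log(stage: str, t0: float, verbose: bool):
    if verbose:
        print(f"[conformap] {stage}: {time.perf_counter() - t0:.2f}s",
              file=sys.stderr)


def _hbond_diff(bonds_wt, bonds_mut, residue_map: ResidueMap) -> pd.DataFrame:
    """Presence/absence diff of hydrogen bonds, in wild-type numbering.

    Mutant bonds are translated back through the residue map; bonds
    touching unmapped residues (e.g. the new copy of a duplication) are
    kept under mutant numbering and flagged.
    """
    back = residue_map.backward
    wt_keys = {b.key: b for b in bonds_wt}
    mut_keys: dict[tuple, Any] = {}
    unmappable = []
    for b in bonds_mut:
        dw, aw = back.get(b.donor_residue), back.get(b.acceptor_residue)
        if dw is None or aw is None:
            unmappable.append(b)
            continue
        mut_keys[(dw, b.donor_atom, aw, b.acceptor_atom)] = b
    rows = []
    for key in sorted(set(wt_keys) | set(mut_keys)):
        in_wt, in_mut = key in wt_keys, key in mut_keys
        status = "kept" if in_wt and in_mut else ("lost" if in_wt else "gained")
        d_wt = wt_keys[key].distance if in_wt else float("nan")
        d_mut = mut_keys[key].distance if in_mut else float("nan")
        rows.append((*key, status, d_wt, d_mut, False))
    for b in unmappable:
        rows.append((*b.key, "gained_unmapped", float("nan"), b.distance, True))
    return pd.DataFrame(rows, columns=[
        "donor_residue", "donor_atom", "acceptor_residue", "acceptor_atom",
        "status", "distance_wt_A", "distance_mut_A", "flagged"])


def compare_alleles(wt_ensemble: Ensemble | Structure,
                    mut_ensemble: Ensemble | Structure,
                    residue_map: ResidueMap | None = None,
                    duplication: tuple[int, int] | None = None,
                    config: AnalysisConfig = AnalysisConfig(),
                    verbose: bool = False) -> dict[str, Any]:
    """Run the full wild-type vs mutant comparison.

    Inputs may be ensembles (time-averaged first) or single structures.
    For unequal-length alleles either an explicit ``residue_map`` or a
    ``duplication`` (dup_start, dup_end) is required.

    Returns a bundle: time-averaged structures, the distance-difference
    map with per-domain block means, the wild-type interface pairs with a
    per-pair separation report, per-residue displacements, RSA changes,
    the hydrogen-bond diff, and a JSON-serializable ``summary``.
    """
    t0 = time.perf_counter()
    avg_wt = (time_average(wt_ensemble) if isinstance(wt_ensemble, Ensemble)
              else wt_ensemble)
    avg_mut = (time_average(mut_ensemble) if isinstance(mut_ensemble, Ensemble)
               else mut_ensemble)
    _log("time_average", t0, verbose)

    if residue_map is None:
        if duplication is not None:
            residue_map = map_from_duplication(
                avg_wt.n_residues, duplication[0], duplication[1])
        elif avg_wt.n_residues == avg_mut.n_residues:
            residue_map = ResidueMap.identity(avg_wt.residue_indices)
        else:
            raise ValueError(
                "alleles differ in length "
                f"({avg_wt.n_residues} vs {avg_mut.n_residues} residues); "
                "provide a residue map (--map) or a duplication range "
                "(--duplication)")

    t0 = time.perf_counter()
    ddm = distance_diff_map(avg_wt, avg_mut, residue_map, metric=config.diff_metric)
    blocks = diff_block_summary(ddm, config.domain_a, config.domain_b)
    _log("distance_diff_map", t0, verbose)

    t0 = time.perf_counter()
    pairs = find_interface_pairs(avg_wt, config.domain_a, config.domain_b,
                                 config.contact)
    pairs_mut = find_interface_pairs(
        avg_mut,
        DomainSpec(config.domain_a.name,
                   _mapped_ranges(config.domain_a, residue_map)),
        DomainSpec(config.domain_b.name,
                   _mapped_ranges(config.domain_b, residue_map)),
        config.contact)
    pair_report = pair_distance_report(avg_wt, avg_mut, pairs, residue_map)
    _log("interface_pairs", t0, verbose)

    t0 = time.perf_counter()
    displacement = per_residue_displacement(
        avg_wt, avg_mut, residue_map,
        frame_selection=config.frame_residues(),
        representative=config.displacement_representative)  # type: ignore[arg-type]
    disp_df = displacement_table(displacement)
    _log("displacement", t0, verbose)

    t0 = time.perf_counter()
    rsa_wt = residue_rsa(avg_wt, config.sasa)
    rsa_mut = residue_rsa(avg_mut, config.sasa)
    rsa_diff = rsa_delta(rsa_wt, rsa_mut, residue_map)
    _log("sasa", t0, verbose)

    t0 = time.perf_counter()
    bonds_wt = find_hbonds(avg_wt, config.hbond)
    bonds_mut = find_hbonds(avg_mut, config.hbond)
    hb_diff = _hbond_diff(bonds_wt, bonds_mut, residue_map)
    _log("hbonds", t0, verbose)

    key = [r for r in config.key_residues if r in set(disp_df.wt_residue)]
    key_disp = disp_df[disp_df.wt_residue.isin(key)]
    max_row = disp_df.loc[disp_df.displacement_A.idxmax()]
    summary = {
        "config": config.to_dict(),
        "n_residues_wt": avg_wt.n_residues,
        "n_residues_mut": avg_mut.n_residues,
        "n_mapped_residues": len(residue_map),
        "diff_block_means_A": blocks,
        "n_interface_pairs_wt": len(pairs),
        "n_interface_pairs_mut": len(pairs_mut),
        "rms_pair_distance_wt_A": pair_report.attrs["rms_distance_a"],
        "rms_pair_distance_mut_A": pair_report.attrs["rms_distance_b"],
        "max_displacement_A": float(max_row.displacement_A),
        "max_displacement_residue": int(max_row.wt_residue),
        "no_displacement": bool(disp_df.displacement_A.max() < 1e-6),
        "key_residue_displacement_A": {
            int(r.wt_residue): float(r.displacement_A)
            for r in key_disp.itertuples()},
        "key_residue_rsa": {
            int(r.wt_residue): {"rsa_wt": r.rsa_wt, "rsa_mut": r.rsa_mut,
                                "bin_wt": r.bin_wt, "bin_mut": r.bin_mut}
            for r in rsa_diff[rsa_diff.wt_residue.isin(key)].itertuples()},
        "n_hbonds_wt": len(bonds_wt),
        "n_hbonds_mut": len(bonds_mut),
        "hbonds_lost": int((hb_diff.status == "lost").sum()),
        "hbonds_gained": int((hb_diff.status == "gained").sum()),
    }
    return {
        "avg_wt": avg_wt,
        "avg_mut": avg_mut,
        "residue_map": residue_map,
        "distance_diff_map": ddm,
        "interface_pairs": pairs,
        "interface_pairs_mut": pairs_mut,
        "pair_report": pair_report,
        "displacement": disp_df,
        "rsa_wt": rsa_table(rsa_wt),
        "rsa_mut": rsa_table(rsa_mut),
        "rsa_delta": rsa_diff,
        "hbond_wt": hbond_table(bonds_wt),
        "hbond_mut": hbond_table(bonds_mut),
        "hbond_diff": hb_diff,
        "summary": summary,
    }


def _mapped_ranges(domain: DomainSpec, residue_map: ResidueMap) -> list[list[int]]:
    """Translate a wild-type domain into mutant-numbering intervals."""
    mapped = sorted(domain.shifted(residue_map))
    if not mapped:
        return []
    ranges: list[list[int]] = [[mapped[0], mapped[0]]]
    for r in mapped[1:]:
        if r == ranges[-1][1] + 1:
            ranges[-1][1] = r
        else:
            ranges.append([r, r])
    return ranges


def write_reports(bundle: dict[str, Any], outdir: str | Path) -> list[Path]:
    """Write the compare_alleles bundle as TSV/CSV reports + summary JSON."""
    from .pdbio import write_pdb

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(name: str, text: str):
        p = out / name
        p.write_text(text)
        written.append(p)

    save("avg_wt.pdb", write_pdb(bundle["avg_wt"]))
    save("avg_mut.pdb", write_pdb(bundle["avg_mut"]))
    save("residue_map.tsv", bundle["residue_map"].to_tsv())
    save("distance_diff_map.csv", bundle["distance_diff_map"].to_csv())
    save("distance_diff_long.tsv",
         bundle["distance_diff_map"].to_long().to_csv(sep="\t", index=False))
    save("interface_pairs.tsv",
         interface_pair_table(bundle["interface_pairs"]).to_csv(sep="\t", index=False))
    save("pair_report.tsv", bundle["pair_report"].to_csv(sep="\t", index=False))
    save("displacement.tsv", bundle["displacement"].to_csv(sep="\t", index=False))
    save("rsa_wt.tsv", bundle["rsa_wt"].to_csv(sep="\t", index=False))
    save("rsa_mut.tsv", bundle["rsa_mut"].to_csv(sep="\t", index=False))
    save("rsa_delta.tsv", bundle["rsa_delta"].to_csv(sep="\t", index=False))
    save("hbond_diff.tsv", bundle["hbond_diff"].to_csv(sep="\t", index=False))
    save("summary.json", json.dumps(bundle["summary"], indent=2, default=float))
    return written
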