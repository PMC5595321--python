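"""File formats.

Regions travel as FASTA, interval annotation as BED (3+ columns,
0-based half-open starts per BED convention), binding sites as BED-6 with
the PWM score in the score column, PWMs as tab-separated 4-column matrices
with a ``>name<TAB>dialect`` header (dialect ``counts`` or ``logodds``),
model parameters as YAML, and tabular data (TF profiles, solutions, SNP
tables, score tables) as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import PWM, BindingSite, RegulatoryRegion
from .dynamics import DynParams, GeneDynParams, GridSpec, TFProfiles
from .thermo import RegulationParams, TFParams, ThermoParams

__all__ = [
    "read_fasta", "write_fasta", "read_bed", "write_bed",
    "read_pwms", "write_pwms", "read_sites_bed", "write_sites_bed",
    "read_params", "write_params", "read_profiles", "write_profiles",
    "read_regions", "write_regions",
]


def read_fasta(path):
    """Sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences):
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path):
    """Intervals per chrom/name: {name: [(start, end), ...]} (0-based)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            out.setdefault(chrom, []).append((start, end))
    return out


def write_bed(path, intervals):
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for start, end in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\n")


def write_sites_bed(path, sites):
    """Sites as BED-6: chrom = gene, name = TF[:model|nonmodel], score = P_s."""
    with open(path, "w") as fh:
        for s in sites:
            flag = "model" if s.is_model else "nonmodel"
            fh.write(
                f"{s.gene}\t{s.start}\t{s.end}\t{s.tf_name}:{flag}\t"
                f"{s.score:.6f}\t{s.strand}\n"
            )


def read_sites_bed(path):
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            gene, start, end, name, score, strand = line.rstrip("\n").split("\t")
            tf, flag = name.rsplit(":", 1)
            sites.append(
                BindingSite(tf_name=tf, gene=gene, start=int(start),
                            end=int(end), strand=strand, score=float(score),
                            is_model=flag == "model")
            )
    return sites


def write_pwms(path, pwms, dialect="logodds", counts=None):
    """One file, one block per TF: '>name<TAB>dialect' then k rows A C G T."""
    with open(path, "w") as fh:
        for tf in sorted(pwms):
            pwm = pwms[tf]
            if dialect == "logodds":
                mat = pwm.logodds
            elif dialect == "counts":
                if counts is None or tf not in counts:
                    raise ValueError(f"no count matrix for {tf}")
                mat = np.asarray(counts[tf])
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            fh.write(f">{tf}\t{dialect}\n")
            for row in mat:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


def read_pwms(path, background=None, pseudocount=0.5):
    """Read PWM blocks; count matrices are converted with the pseudocount."""
    if background is None:
        background = np.full(4, 0.25)
    pwms = {}
    name, dialect, rows = None, None, []

    def flush():
        if name is None:
            return
        mat = np.array(rows, dtype=float)
        if dialect == "counts":
            pwms[name] = PWM.from_counts(name, mat, background, pseudocount)
        else:
            pwms[name] = PWM(name, mat, np.asarray(background, float))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split("\t")
                name = parts[0].strip()
                dialect = parts[1].strip() if len(parts) > 1 else "logodds"
                rows = []
            else:
                rows.append([float(x) for x in line.split()])
    flush()
    return pwms


def write_params(path, thermo: ThermoParams, dyn: DynParams, grid: GridSpec):
    doc = {
        "thermo": {
            "btm_basal_weight": thermo.btm_basal_weight,
            "normalize_by_max": thermo.normalize_by_max,
            "omega_per_pair": thermo.omega_per_pair,
            "tf": {
                tf: {"K": p.K, "omega": p.omega, "coop_range": p.coop_range}
                for tf, p in thermo.tf.items()
            },
            "regulation": {
                f"{tf}|{gene}": {
                    "role": p.role,
                    **({"alpha": p.alpha} if p.role == "activator"
                       else {"beta": p.beta, "rep_range": p.rep_range}),
                }
                for (tf, gene), p in thermo.regulation.items()
            },
        },
        "dynamics": {
            gene: {
                "r_u": p.r_u, "r_v": p.r_v,
                "lambda_u": p.lambda_u, "lambda_v": p.lambda_v,
                "d_u": {str(k): v for k, v in p.d_u.items()},
                "d_v": {str(k): v for k, v in p.d_v.items()},
                "tau": p.tau,
            }
            for gene, p in dyn.genes.items()
        },
        "grid": {
            "nuclei_c13": grid.nuclei_c13,
            "duration_c13": grid.duration_c13,
            "duration_c14a": grid.duration_c14a,
            "output_times": list(grid.output_times),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_params(path):
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    t = doc["thermo"]
    thermo = ThermoParams(
        tf={
            tf: TFParams(K=d["K"], omega=d.get("omega", 1.0),
                         coop_range=d.get("coop_range", 0))
            for tf, d in t["tf"].items()
        },
        regulation={
            tuple(key.split("|")): RegulationParams(
                role=d["role"], alpha=d.get("alpha"), beta=d.get("beta"),
                rep_range=d.get("rep_range", 0),
            )
            for key, d in t["regulation"].items()
        },
        btm_basal_weight=t.get("btm_basal_weight", 1.0),
        normalize_by_max=t.get("normalize_by_max", True),
        omega_per_pair=t.get("omega_per_pair", False),
    )
    dyn = DynParams(
        genes={
            gene: GeneDynParams(
                r_u=d["r_u"], r_v=d["r_v"],
                lambda_u=d["lambda_u"], lambda_v=d["lambda_v"],
                d_u={int(k): v for k, v in d["d_u"].items()},
                d_v={int(k): v for k, v in d["d_v"].items()},
                tau=d.get("tau", 0.0),
            )
            for gene, d in doc["dynamics"].items()
        }
    )
    g = doc["grid"]
    grid = GridSpec(
        nuclei_c13=g["nuclei_c13"], duration_c13=g["duration_c13"],
        duration_c14a=g["duration_c14a"],
        output_times=tuple(g["output_times"]),
    )
    return thermo, dyn, grid


def write_profiles(path, profiles: TFProfiles):
    profiles.to_frame().to_csv(path, sep="\t", index=False)


def read_profiles(path) -> TFProfiles:
    return TFProfiles.from_frame(pd.read_csv(path, sep="\t"))


def write_regions(outdir, regions):
    """FASTA + accessibility/CDS BED files for a dict of regions."""
    outdir = Path(outdir)
    write_fasta(outdir / "regions.fa",
                {r.gene: r.sequence for r in regions.values()})
    write_bed(outdir / "accessible.bed",
              {r.gene: r.accessible for r in regions.values()})
    write_bed(outdir / "cds.bed", {r.gene: r.cds for r in regions.values()})


def read_regions(outdir):
    outdir = Path(outdir)
    seqs = read_fasta(outdir / "regions.fa")
    acc = read_bed(outdir / "accessible.bed")
    cds = read_bed(outdir / "cds.bed")
    return {
        gene: RegulatoryRegion(
            gene=gene, sequence=seq,
            accessible=acc.get(gene, []), cds=cds.get(gene, []),
        )
        for gene, seq in seqs.items()
    }
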