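"""Readers and writers for the formats shared by all stages.

FASTA for promoter sequences (5'->3', TSS at the 3' end), whitespace tables
for frequency matrices, YAML for models and run configuration, TSV with
headers for every tabular artifact, and BED for masked-fill intervals.
"""

from __future__ import annotations

from typing import Dict, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import SignatureModel, model_from_dict, model_to_dict


def read_fasta(path) -> Dict[str, str]:
    """Read promoters as an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, promoters: Dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="")
               for pid, seq in promoters.items()]
    SeqIO.write(records, str(path), "fasta")


def read_model(path) -> SignatureModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def write_model(path, model: SignatureModel) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def read_expression_table(path) -> pd.Series:
    """TSV with header; first column ORF ids, second log fold-change."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0],
                     name="change")


def write_expression_table(path, expression: pd.Series) -> None:
    expression.rename_axis("orf").rename("change").to_frame().to_csv(
        path, sep="\t")


def read_pvalue_table(path) -> pd.DataFrame:
    """TSV with header; first column promoter ids, one column/condition."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_pvalue_table(path, table: pd.DataFrame) -> None:
    table.rename_axis("promoter").to_csv(path, sep="\t")


def write_mask_bed(path, masks: Dict[str, Sequence[tuple]]) -> None:
    """Masked-fill intervals as BED3 (promoter, start, end)."""
    with open(path, "w") as fh:
        for pid, intervals in masks.items():
            for lo, hi in intervals:
                fh.write(f"{pid}\t{lo}\t{hi}\n")


def read_mask_bed(path) -> Dict[str, list]:
    masks: Dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            pid, lo, hi = line.split()[:3]
            masks.setdefault(pid, []).append((int(lo), int(hi)))
    return masks


def write_posterior_track(path, promoter_id: str, site_start) -> None:
    """Site-start posteriors as TSV (promoter, position, strand, posterior)."""
    with open(path, "w") as fh:
        fh.write("promoter\tposition\tstrand\tsite_start_posterior\n")
        for i in range(site_start.shape[0]):
            for s, strand in enumerate("+-"):
                fh.write(f"{promoter_id}\t{i}\t{strand}\t"
                         f"{site_start[i, s]:.6g}\n")


def write_ranking(path, ranked) -> None:
    df = ranked.table.copy()
    df.insert(1, "method", ranked.method)
    df.rename(columns={"id": "promoter"}).to_csv(path, sep="\t", index=False)


def write_sites_table(path, sites: pd.DataFrame) -> None:
    sites.to_csv(path, sep="\t", index=False)
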