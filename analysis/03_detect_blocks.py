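"""Detect haplotype blocks in Stage 1 and confirm the boundaries in Stage 2.

Gabriel-style detection (D' confidence bounds 0.98/0.70, max 15 markers in
160 kb) on each stage independently: the three generating blocks should be
recovered in both, up to SNPs whose rarest haplotypes leave wide D'
confidence intervals.  Stage 1 block definitions are exported for reuse in
the association step (mirroring the detect-in-stage-1 / apply-to-stage-2
design).
"""

import json
import sys
from pathlib import Path

from hapblock import io, ld, qc

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def main() -> None:
    for stage in ("stage1", "stage2"):
        variants, genotypes, _ = io.read_vcf(SCRATCH / f"{stage}.vcf")
        vkeep, skeep, _ = qc.run_qc_chain(genotypes, variant_table=variants,
                                          check_ibd=False)
        g = genotypes[skeep][:, vkeep]
        v = variants.loc[vkeep].reset_index(drop=True)
        bs = ld.gabriel_blocks(g, v["pos"].to_numpy())
        ld.write_block_tsv(bs, v, RESULTS / f"03_blocks_{stage}.tsv")
        ld.write_block_bed(bs, v.iloc[0]["chrom"],
                           RESULTS / f"03_blocks_{stage}.bed")
        print(f"{stage}: {len(bs)} blocks: "
              + "; ".join(f"{b.start}-{b.stop} ({b.n_snps} SNPs)"
                          for b in bs))
        if stage == "stage1":
            from hapblock.pipeline import block_definitions

            defs = block_definitions(bs, v)
            (RESULTS / "03_stage1_block_definitions.json").write_text(
                json.dumps(defs, indent=2))
            print("exported Stage 1 block definitions for reuse")


if __name__ == "__main__":
    sys.exit(main())
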