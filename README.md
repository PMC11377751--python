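# gmdomains

Discovery of candidate genome-maintenance (GM) protein domains by
profile-HMM remote-homology search with reciprocal validation.

Genome maintenance — DNA repair, the DNA damage response (DDR), and
mitotic/chromosome-segregation fidelity — is carried by proteins whose
domains are often too diverged for pairwise sequence search to find.
Profile hidden Markov models, which carry position-specific residue
probabilities and position-specific insertion/deletion costs, recover such
remote homologies. This package implements, as a tested and reusable
library plus CLI, the full discovery protocol around that idea:

1. **Candidate compilation** — pooling proteins annotated with four GM GO
   terms (GO:0006281 DNA repair, GO:0006974 DNA damage response,
   GO:0000910 cytokinesis, GO:0000278 mitotic cell cycle) across species,
   with child-term propagation; mining interaction tables for pairs that
   join one DNA-repair-annotated protein to a DDR-naive partner with
   experimental evidence in ≥2 publications, minus housekeeping genes and
   recurrent proteomics contaminants; and mining per-tissue co-expression
   modules for gene pairs recurring in ≥2 tissues, filtered by the same
   protocol.
2. **Masked, iterative profile-HMM search** — coiled-coil (heptad-repeat)
   and low-complexity masking; per query an iteratively enriched MSA
   (inclusion at E ≤ 0.01), a profile HMM, and a profile-to-profile search
   against a domain-family library scored by the co-emission column score
   `S(i,j) = log2 Σ_a e_q[i][a] e_t[j][a] / f[a]`; E-values from a Gumbel
   fit to decoy scores, `E(s) = n_db · P(S ≥ s)`.
3. **Reciprocal validation and curation** — a hit is accepted only when a
   profile seeded from the hit's family region significantly (E ≤ 0.01)
   re-finds the query over at least half of the forward region; candidate
   MSAs can be curated (diversity filter to >30 sequences, insert removal,
   problem-region elimination) and re-searched, recovering the same
   families.
4. **Synthetic worlds with ground truth** — planted domain families at
   controlled identity, planted sequence features, GO DAGs, interaction
   tables and expression matrices with known modules, so recovery, error
   rates and calibration are measured end to end.

Everything is driven by explicit seeds; there is no global random state.

## Worked example

Simulate a 25-member domain family (90-residue domain, member-to-ancestor
identity 0.45, i.e. member-to-member ≈ 20%) planted into proteins among 40
decoys, build a profile from the family alignment, and search the proteome:

```
$ gmdomains simulate --config sim.yaml --outdir world --seed 11
wrote simulation to world
$ gmdomains buildhmm --msa world/nucA.sto --out nucA.hmm
90 match states -> nucA.hmm
$ gmdomains hmmsearch --hmm nucA.hmm --db world/proteins.fasta \
      --emax 0.01 --seed 5 --out hits.tsv
25 hits -> hits.tsv
$ head -4 hits.tsv
query     target    q_start  q_end  t_start  t_end  bits     E
nucA_m00  nucA_m19  3        90     57       145    104.707  1.2e-41
nucA_m00  nucA_m14  1        90     66       155    99.5601  1.0e-39
nucA_m00  nucA_m08  2        90     33       123    98.6227  2.4e-39
```

All 25 planted family members are recovered — each hit names the member
protein, the matched profile columns (`q_start..q_end`), the residue
interval on the target protein (`t_start..t_end` locates the planted domain
behind its random linker), the bit score, and the E-value (expected number
of equal-or-better decoy hits in this database) — and none of the 40 decoy
proteins appears at E ≤ 0.01.

The same workflow in library form: `generate_family` / `plant_proteins`
(synthetic worlds), `hmm_from_msa` / `search` / `calibrate_evd` (engine),
`run_discovery` (masking + iterative MSAs + forward + reciprocal), and
`run_benchmark` (planted-truth scoring). `filter-ppi`, `coexpress`, `mask`,
`hhalign`, `tree` and `identity` expose the remaining stages.

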