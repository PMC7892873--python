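"""Simulate a three-generation multiplex family with a planted dominant variant.

Builds the default pedigree (7 affected, 3 unaffected genotyped members),
drops 200 background exome variants through it by Mendelian transmission,
plants one fully penetrant dominant missense variant, and prints the
planted variant's dosage in every genotyped member.
"""

from famrare.simulate import FamilySimConfig, simulate_family

result = simulate_family(FamilySimConfig(seed=1))
planted = result.truth.query("role == 'planted'").variant_key.iloc[0]
print(f"planted variant: {planted}")
print(f"variants simulated: {len(result.variants)}")
print("member  affection   dosage")
col = result.genotypes.dosage_vector(planted)
for member in result.pedigree:
    if member.individual_id not in result.genotypes.sample_ids:
        continue
    d = col[result.genotypes.sample_index(member.individual_id)]
    print(f"{member.individual_id:<7} {member.affection:<11} {d}")

# Every affected member is heterozygous (dosage 1) and every unaffected
# member carries no copy (dosage 0): the pattern a fully penetrant dominant
# allele must show, and the signal the cosegregation filter looks for.
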