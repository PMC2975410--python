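"""Up-propagate gene annotations along a term DAG and group terms by size.

A gene annotated to a term is implicitly annotated to every ancestor
(true-path rule); per-term positive counts then map each term to one of
four annotation-size groups that control the oversampling schedule.
"""

from genepu import AnnotationSet, enlargement_times, group_terms_by_size, propagate_annotations

ann = AnnotationSet(
    assignments={("gene1", "kinase"), ("gene2", "kinase"), ("gene3", "hydrolase"),
                 ("gene4", "catalytic")},
    dag={("molecular_function", "catalytic"), ("catalytic", "kinase"),
         ("catalytic", "hydrolase")},
)
print(f"direct annotations: {len(ann.assignments)}")

full = propagate_annotations(ann)
print(f"after up-propagation: {len(full.assignments)} "
      "(each gene now also annotated to all ancestor terms)")
for gene in sorted({g for g, _ in full.assignments}):
    terms = sorted(t for g, t in full.assignments if g == gene)
    print(f"  {gene}: {', '.join(terms)}")

print("\nterm sizes and groups (half-open boundaries [0,60), [60,100), [100,300), [300,inf)):")
for tg in group_terms_by_size(full):
    times = enlargement_times(tg.positive_count)
    print(f"  {tg.term}: {tg.positive_count} genes -> group '{tg.group_label}', "
          f"oversampling schedule {times}x")
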