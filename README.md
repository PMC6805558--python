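# medrqe

Entailment-based question answering for consumer-health questions.

Consumer questions ("My son has to get tested for WPW — can you send me
information about this condition?") are long, noisy and multi-part, while
institutional FAQ collections hold short canonical questions with curated
answers.  `medrqe` bridges the two with *Recognizing Question Entailment*
(RQE): a premise question PQ entails a hypothesis question HQ when every
answer to HQ is a complete or partial answer to PQ.  Instead of searching
answers directly, the system retrieves candidate questions from an
expanded index, keeps those the user's question entails, and returns their
answers.

The pipeline:

1. **Retrieval** — questions (not answers) are indexed together with their
   focus synonyms and question-type trigger phrases; TF-IDF and the
   In-expB2 Divergence-From-Randomness model each rank the top N = 100
   candidates and the lists are fused by summing scores (CombSUM).
2. **Entailment** — logistic regression over ten lexical features (overlap
   coefficient, bigram Dice, cosine, Levenshtein, Jaccard, their max and
   mean, length ratio, shared noun/verb count, question-type agreement)
   scores each (PQ, HQ) pair; non-entailed candidates are dropped.
3. **Hybrid reranking** — Hscore_k = α·Norm_k(IR) + β·Norm_k(RQE) with
   α = β = 0.5, each score max-normalized over the candidate pool; the
   top-k surviving answers are returned (IR-order fallback if nothing is
   entailed).

Evaluation utilities implement the TREC-LiveQA measures — avgScore(0–3),
succ@i+/prec@i+, MAP@10 and MRR@10 with correctness = grade 3 or 4 — plus
assessor-agreement F1 (recall fixed at 100%, so F1 = 2P/(1+P)).  A seeded
fixture generator produces QA collections, consumer-style premise
variants, and labeled entailment pairs (positive ⇔ same focus and
overlapping question type) so everything is testable offline.

## Worked example

```bash
medrqe gen-fixtures --out fix/ --seed 5 --n-topics 8 --types-per-topic 3 --n-pairs 200
medrqe train-rqe --pairs fix/pairs.tsv --out model.json --seed 5
medrqe build-index --collection fix/qa.jsonl --out index.json
medrqe ask --index index.json --model model.json --collection fix/qa.jsonl \
    --question "My mother was told she has cigreskith last month and we are very worried. What are the treatments for cigreskith?" \
    --top-k 3
```

prints

```
[1] (1.000) Curated answer about the treatment of cigreskith. [cigreskith|Treatment]
```

Despite the added context sentence, only the matching collection question
"What are the treatments for cigreskith?" is classified as entailed, and
it holds both the IR and the RQE pool maxima, so its hybrid score is
exactly 1.0.  The bracketed `[focus|type]` suffix is the fixture
generator's gold key.  Rephrasing with a trigger synonym,

```bash
medrqe ask ... --question "My mother was told she has cigreskith last month \
and we are very worried. What are the remedies for cigreskith?" --top-k 3
```

```
[1] (13.368) Curated answer about the treatment of cigreskith. [cigreskith|Treatment]
[2] (8.201) Curated answer about the inheritance of cigreskith. [cigreskith|Inheritance]
[3] (7.985) Curated answer about the diagnosis of cigreskith. [cigreskith|Diagnosis]
```

here the lexical entailment filter accepts nothing (the paraphrase shares
too few tokens), so the system falls back to the fused IR ranking — raw
fused scores, not normalized hybrids — where the trigger tokens indexed
with each question still put the treatment answer first.

The same pieces are available as a library:

```python
from medrqe import (FixtureSpec, generate_collection, generate_rqe_pairs,
                    load_default_taxonomy, train_lr, build_index, answer_question)

tax = load_default_taxonomy()
spec = FixtureSpec(seed=5)
records = generate_collection(spec, tax)
model = train_lr(generate_rqe_pairs(records, spec, tax), seed=5)
index = build_index(records, tax)
result = answer_question("What causes " + records[0].question.focus + "?",
                         index, model, records, taxonomy=tax)
print(result.answers[0].answer)
```

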