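# respstyles

Can you tell from Likert questionnaire data whether extreme and midpoint
response styles are two poles of a single trait, or two separate traits —
or absent altogether?  `respstyles` implements the adapted multidimensional
nominal response model (MNRM) with fixed scoring matrices, a simulator for
the three competing data-generating structures, a marginal-maximum-likelihood
estimator, and AIC/BIC model-classification machinery for answering that
question by Monte-Carlo simulation or on your own response tables.

It is aimed at psychometricians and survey methodologists who analyse
five-point (or any odd-K) Likert scales and need to decide how — and whether
— to model extreme responding (ERS, a preference for the endpoint categories)
and midpoint responding (MRS, a preference for the middle category).

## The model

The probability that respondent *p* endorses category *k* of item *i* is a
softmax over categories,

    P(Y_i = k | θ) ∝ exp([a_i ⊙ s_k]ᵀ θ + c_ik),

where `θ` is the vector of latent scores (substantive traits first, then
response-style traits), `a_i` the item's slope vector, `c_ik` category
intercepts, and `s_k` the *k*-th column of a fixed scoring matrix `s` with one
row per latent dimension.  For five categories the scoring rows are

| model          | rows of `s` |
|----------------|-------------|
| `null`         | substantive (0 1 2 3 4) — reduces to the generalized partial credit model |
| `ers_mrs`      | substantive (0 1 2 3 4); bipolar style (2 1 0 1 2) |
| `ers_plus_mrs` | substantive (0 1 2 3 4); ERS (1 0 0 0 1); MRS (0 0 1 0 0) |

Latent traits are multivariate normal with zero means, unit variances and
freely estimated correlations.  Fitting maximizes the marginal likelihood
(traits integrated out by Gauss–Hermite quadrature) with an EM algorithm;
models are compared by AIC = −2ℓ + 2p and BIC = −2ℓ + p·ln N, and a combined
rule uses the BIC to detect any response style and then the AIC to pick
between the bipolar and two-dimensional structures.

## Worked example

```python
from respstyles import GenCondition, fitted_model_battery, generate_dataset
from respstyles.selection import criterion_table
from respstyles.study import STUDY_FIT_OPTIONS

condition = GenCondition("ers_plus_mrs", 1000, 20, 1, sigma_rs=1.0,
                         r_rs=0.5, slope_corr=0, seed=3)
data, *_ = generate_dataset(condition)
fits = fitted_model_battery(data, options=STUDY_FIT_OPTIONS)
print(criterion_table(fits).to_string(index=False))
```

prints

```
       model        loglik  n_params          aic          bic  selected_aic  selected_bic  selected_combined
        null -26040.561179       100 52281.122358 52771.897886         False         False              False
     ers_mrs -25597.863274       121 51437.726549 52031.564937         False         False              False
ers_plus_mrs -24895.772071       143 50077.544142 50779.353147          True          True               True
```

The data were generated with two separate, correlated response-style
dimensions; both criteria (and the combined rule) correctly prefer the
`ers_plus_mrs` model — its ~700-unit log-likelihood advantage over the
bipolar model dwarfs the 22-parameter penalty.  The `examples/` directory
walks through probability curves, parameter recovery, reduced Monte-Carlo
studies and the person/item resampling design; a thin `respstyles` CLI
(`simulate`, `fit`, `compare`, `study`, `resample`) wraps the same calls for
shell use.

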