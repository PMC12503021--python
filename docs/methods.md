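# Methods

## Model

For subject $i$ with responses $y_i \in \mathbb{R}^{n_i}$ at times $t_i$,

$$y_i = B(t_i)\,\beta_i + \varepsilon_i, \qquad \varepsilon_i \sim N(0, \sigma^2 I_{n_i}),$$

where $B(t_i)$ is an $n_i \times d$ design matrix of basis functions
(Legendre polynomials on an affinely rescaled domain, or periodic-seasonal
plus trend cubic B-splines) and $\beta_i$ is a subject-specific coefficient
vector.  Nothing ties $n_i$ to $d$; subjects with $n_i < d$, down to a
single observation, are handled by the same formulas because every update
involves only $B_i^\top B_i$ and $B_i^\top y_i$.

The prior for $\beta_i$ is a deep mixture of factor analyzers (DMFA).
Writing $z^{(0)} = \beta_i$, each layer $l = 1 \dots L$ draws a component
$k_l$ with probability $w^{(l)}_{k_l}$ and sets

$$z^{(l-1)} = \mu^{(l)}_{k_l} + B^{(l)}_{k_l} z^{(l)} + \epsilon^{(l)}, \qquad
\epsilon^{(l)} \sim N(0, \mathrm{diag}\,\delta^{(l)}_{k_l}),$$

with $z^{(L)} \sim N(0, I)$ and lower-triangular loadings.  Dimensions must
satisfy $D^{(l+1)} \le (D^{(l)}-1)/2$ (the Anderson–Rubin identifiability
condition), which is enforced at construction.  Marginalising the latent
chain collapses the prior into an explicit Gaussian mixture over "paths"
$(k_1,\dots,k_L)$ with

$$w_k = \prod_l w^{(l)}_{k_l}, \quad
\mu_k = \mu^{(1)}_{k_1} + \sum_{l\ge2} P_{l-1}\mu^{(l)}_{k_l}, \quad
\Sigma_k = \mathrm{diag}\,\delta^{(1)}_{k_1}
 + \sum_{l\ge2} P_{l-1}\,\mathrm{diag}\,\delta^{(l)}_{k_l}\,P_{l-1}^\top
 + P_L P_L^\top,$$

where $P_l = B^{(1)}_{k_1}\cdots B^{(l)}_{k_l}$.  The final term carries the
top-layer $N(0,I)$ variance; the single-layer special case
$\Sigma_k = B_k B_k^\top + \mathrm{diag}\,\delta_k$ requires it, and the
Monte-Carlo sampling oracle in the test suite confirms the full recursion.
All predictive quantities are Gaussian-mixture algebra on this collapsed
form: the subject marginal likelihood, the conditional law of unobserved
responses given observed ones (per-component Gaussian conditioning with the
$\sigma^2 I$ observation term included in the conditioning covariance), the
pointwise mixture CDF, quantiles and moments.

## Priors

All heavy-tailed priors are carried in their inverse-gamma scale-mixture
representations, which is what makes every variational update conjugate:

| parameter | prior | representation | default scale |
|---|---|---|---|
| error sd $\sigma$ | half-Cauchy$(A)$ | $\sigma^2\mid\psi \sim IG(\frac12, 1/\psi)$, $\psi \sim IG(\frac12, 1/A^2)$ | $A=5$ |
| mean entries $\mu$ | Cauchy$(0, c_\mu)$ | $\mu\mid\lambda \sim N(0,\lambda)$, $\lambda \sim IG(\frac12, c_\mu^2/2)$ | $c_\mu = 2.5$ |
| noise sds $\sqrt{\delta}$ | half-Cauchy$(c_\delta)$ | as for $\sigma$ | $c_\delta = 2.5$ |
| loadings $b$ | horseshoe | $b \sim N(0, v_{loc} v_{glob})$, each variance half-Cauchy via IG–IG | global scale 1 |
| weights $w^{(l)}$ | Dirichlet$(\alpha,\dots,\alpha)$ | — | $\alpha = 1/2$ |

The scales are weakly informative on a response scale of order one.  The
small Dirichlet concentration drives the overfitted-mixture mechanism:
surplus path components are expected to empty during fitting and are pruned
afterwards (a path is empty when no subject has it as its argmax
responsibility; empty weights are set to zero and the rest rescaled).

## Variational inference

The factorised family uses Gaussian factors for location parameters
(independent entries for $\mu$ and $\beta_i$ — the latter per the model's
stated independent-marginals family — and full covariance per loading row
and per layer latent $z_i^{(l)}$), inverse-gamma factors for every
variance-type parameter and auxiliary, Dirichlet factors for weights, and
one categorical responsibility vector per layer per subject.  Per-layer
responsibilities are exact mean-field factors (given the latent chain the
layer indicators are conditionally independent) and keep the cost per
iteration proportional to $\sum_l K^{(l)}$ rather than $\prod_l K^{(l)}$.

Fitting alternates (i) block coordinate ascent on the local factors of a
minibatch — responsibilities, a Gauss–Seidel sweep over the coordinates of
$q(\beta_i)$, and exact full-covariance updates of each $q(z_i^{(l)})$ —
iterated until the per-subject local objective moves less than $10^{-8}$
(cap 20 sweeps), and (ii) a natural-gradient step on every global factor:
the convex combination $(1-\rho_m)\eta_{old} + \rho_m\eta^*$ of natural
parameters, where $\eta^*$ is the conditionally-conjugate optimum computed
from the minibatch with data statistics rescaled by $n/|S|$.  The schedule
is $\rho_m = (m + \tau)^{-\kappa}$ with $\kappa = 0.75$, $\tau = 10$;
minibatches default to $\min(n, 64)$ without replacement, reshuffled per
epoch.  With a full batch and $\rho = 1$ the loop is exact CAVI and the
ELBO is monotone — asserted to $10^{-6}$ over 200 iterations in the test
suite.  The closed-form ELBO (all expectations analytic under the conjugate
factors) is validated end to end against a Monte-Carlo estimate of
$E_q[\log h(\theta) - \log q(\theta)]$ on a small instance.

Prediction is plug-in: the point estimate takes the q-means of weights,
means, loadings and noise (the inverse-gamma mean when the shape exceeds
one, otherwise the inverse of the mean precision, which only matters for
components that are about to be pruned anyway), collapses them, prunes
empty paths, and sets $\hat\sigma^2$ to the q-mean of $\sigma^2$.

## Initialisation and start selection

Two failure modes of mean-field coordinate ascent shaped the
initialisation, and both were measured during development rather than
assumed:

1. **Zero latent means are a saddle.**  If the latent score means start at
   zero, the loading update's data term vanishes, the loadings collapse to
   zero, the horseshoe then pins them there, and the collapsed prior
   degenerates into a diagonal-covariance mixture.  Each layer is therefore
   initialised from a per-cluster SVD of its input variables (ridge
   coefficients for layer 1, the previous layer's standardized scores
   deeper): loadings are principal directions scaled to component standard
   deviations, latent means are the matching standardized scores, and the
   layer noise starts at the residual variance after removing the factor
   contribution.

2. **Hard k-means over all components locks in sub-optimal splits.**
   Seeding every component splits real clusters into stable sub-optima that
   the overfitted-mixture pruning cannot merge; seeding one component can
   merge real clusters.  The number of initially occupied components per
   layer is therefore selected by short pilot runs scored by the full-data
   ELBO (the same short-run-ELBO device the method uses for architecture
   choice): first the first-layer count from $1..K^{(1)}$, then each deeper
   layer's count given the earlier choices — $\sum_l K^{(l)}$ pilots of 50
   iterations by default.  Unoccupied components start at the global mean
   (jittered) with the global covariance, nearly weightless: available to
   the overfitted mixture, usually starved.

Everything is deterministic given the integer seed, which drives k-means,
symmetry-breaking jitter and minibatch shuffling through one generator.

## Synthetic designs

Three generators define the study conditions (all seed-deterministic):

* **Two-group functional design** — 600 subjects, 10 uniform times on
  $[0,1]$, mean curves $\pm\sin(4\pi t)$, a truncated Karhunen–Loève
  functional error $2\sum_{k=1}^4 \xi_k \sin(k\pi t)$ with
  $\xi_k \sim N(0, sd_k^2)$, $sd = (0.1, 0.045, 0.01, 0.001)$, and noise
  sd 0.3.
* **Stochastic Van der Pol oscillators** — 100 subjects,
  $\theta_i = e^{U(1,5)}$, Euler–Maruyama integration from $t=0$ at
  $dt = 10^{-3}$ with diffusion coefficient 0.5 on both coordinates,
  15–25 observation times on $[10, 20]$ snapped to the integration grid, no
  extra observation noise.  Diverging paths (states beyond $10^6$) are
  regenerated at a halved step and logged.  The zero-diffusion limit is
  checked against a high-accuracy ODE solve (first-order convergence: the
  sup-norm oracle is evaluated at $dt = 10^{-5}$ where the Euler drift is
  below 0.01).
* **Trigonometric imputation design** — 120 subjects on a 40-point grid
  $t_j = (j-1)/39$, $y_{ij} = \beta_{i1}\cos(w_{i1}\pi t_j) +
  \beta_{i2}\sin(w_{i2}\pi t_j) + \varepsilon_{ij}$ with
  $\beta \in \{1, 0.1\}$, $w_1 \in \{1,2,3\}$, $w_2 \in \{7,8,9\}$ (36
  latent clusters), noise sd 0.1; 15–20 points per subject removed and kept
  aside as imputation targets.

These emulate the shapes of real longitudinal data (unbalanced designs,
group structure, chaotic dynamics, missingness) but not other features —
no covariates, no within-subject error correlation, no outliers — so
passing tests bound behaviour only under those idealised conditions.

The benchmark harness fits the default architecture ($d=10$ Legendre,
layers $(10,4,1)$, components $(6,3)$, 1000 iterations — the deep two-layer
setting used throughout) on a training draw and evaluates an independent
test draw: for the first two designs each test subject's points are split
at random (half conditioned on, rounded up; the rest predicted), for the
third the removed grid entries are imputed from the observed ones.
Reported per replication: the log of the subject-averaged RMSE of the
predictive mean against the *noise-free* signal at held-out points (an
RMSE below the noise floor is only meaningful against the signal), and the
negative log-score, the subject-averaged $-\log p$ of each test subject's
full observed vector under the fitted marginal mixture likelihood.  Five
replications are used at desk scale.

## Numerical choices

* Near-singular component covariances receive a $10^{-8}$ diagonal jitter
  before Cholesky factorisation, logged when applied; a still-singular
  matrix raises with the component index.
* Mixture log-densities are per-component Cholesky log-densities combined
  by log-sum-exp; zero-weight components are skipped.
* Mixture quantiles invert the scalar mixture CDF by bisection to
  $10^{-10}$.
* Elliptical credible sets moment-match the predictive mixture to one
  Gaussian and use the chi-square ellipsoid.  For strongly multimodal
  predictives this is miscalibrated; the measured direction for symmetric
  tight modes is *over*-coverage (the matched variance spans the inter-mode
  gap), quantified by Monte Carlo in the tests.
* The divergence in the prior-data-conflict statistic
  $G = D_{KL}(p(\text{future}\mid\text{past}) \,\|\, p(\text{future}))$ has
  no closed form between mixtures; it is estimated by plain Monte Carlo
  from the conditional (2000 draws by default), the reference distribution
  uses replicate past segments from the model's marginal, and the tail
  probability carries an add-one correction $(1 + \#\{G_{rep} \ge
  G_{obs}\})/(1 + n_{sim})$.
* Ties in cluster assignment resolve to the lowest path index; path order
  is lexicographic in $(k_1,\dots,k_L)$ everywhere.

## Known limitations

* The independent-marginals family for $q(\beta_i)$ underestimates
  posterior spread when $B_i^\top B_i$ is far from diagonal; downstream the
  collapsed covariances are mildly shrunk.  This is a property of the
  stated variational family, not of the implementation.
* The evidence lower bound tends to prefer fewer occupied mixture
  components than held-out predictive density would; the start-selection
  procedure follows the ELBO — the model's own criterion — and accepts
  this bias, so fits on data with many weakly separated clusters retain a
  small fraction of the available paths.
* A handful of tail subjects can occupy an otherwise-starved broad
  component, so the number of distinct argmax labels may exceed the number
  of real clusters by one or two small groups even when the partition is
  essentially recovered.
* KL estimation for the conflict check is plain Monte Carlo; very small
  divergences are resolved only up to MC error.
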