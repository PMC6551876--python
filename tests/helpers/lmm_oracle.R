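# Independent oracle for the balanced paired design: fit a random
# donor-intercept mixed model by REML and report the Satterthwaite ANOVA
# F statistic and p-value for the cell-state factor, one row per table.
#
# Usage: Rscript lmm_oracle.R input.csv output.csv
# input.csv columns: table, donor, state, y (long format)

args <- commandArgs(trailingOnly = TRUE)
suppressMessages(library(lmerTest))

d <- read.csv(args[1])
d$donor <- factor(d$donor)
d$state <- factor(d$state)

rows <- lapply(sort(unique(d$table)), function(t) {
  g <- d[d$table == t, ]
  # tight optimizer tolerances: the comparison is at 1e-6 relative and the
  # default stopping rule leaves ~1e-5 relative slack in the F statistic
  m <- lmer(y ~ state + (1 | donor), data = g,
            control = lmerControl(optimizer = "nloptwrap",
                                  optCtrl = list(xtol_abs = 1e-14,
                                                 ftol_abs = 1e-14)))
  a <- anova(m)
  data.frame(table = t,
             F = a[1, "F value"],
             p = a[1, "Pr(>F)"],
             den_df = a[1, "DenDF"])
})
write.csv(do.call(rbind, rows), args[2], row.names = FALSE)
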