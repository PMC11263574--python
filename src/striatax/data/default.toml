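seed = 0
pseudocount = 0.5
de_min_cells = 10

[generator]
n_genes = 6000
samples = [["CN1", "CN"], ["CN2", "CN"], ["CN3", "CN"], ["Pu1", "Pu"], ["Pu2", "Pu"], ["Pu3", "Pu"]]
cells_per_sample = 800
mean_library_size = 35000.0
library_size_dispersion = 0.25
nb_dispersion = 0.25
doublet_rate = 0.05
mito_fraction_mean = 0.03
gene_logmean_sigma = 1.0
heterogeneity_sigma = 1.2
block_share = 0.6
marker_baseline_rate = 2e-05
seed = 0

[[generator.populations]]
name = "CCK/VIP"
marker_genes = ["ADARB2", "CCK", "VIP", "MEG3", "GAD1", "GAD2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.055, Pu = 0.055}
correlation_block = 0
gradient_strength = 1.5

[[generator.populations]]
name = "CCK/VIP/CXCL14"
marker_genes = ["ADARB2", "CCK", "VIP", "CXCL14", "MEG3", "GAD1", "GAD2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.05, Pu = 0.05}
correlation_block = 0
gradient_strength = 1.5

[[generator.populations]]
name = "CCK"
marker_genes = ["ADARB2", "CCK", "MEG3", "GAD1", "GAD2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.04, Pu = 0.09}
correlation_block = 1
gradient_strength = 1.5

[[generator.populations]]
name = "CCK/CHST9"
marker_genes = ["ADARB2", "CCK", "CHST9", "MEG3", "GAD1", "GAD2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.05, Pu = 0.05}
correlation_block = 1
gradient_strength = 1.5

[[generator.populations]]
name = "PVALB"
marker_genes = ["PVALB", "MEG3", "GAD1", "GAD2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.055, Pu = 0.055}
correlation_block = 2
gradient_strength = 1.5

[[generator.populations]]
name = "PVALB/GRIK3"
marker_genes = ["PVALB", "GRIK3", "MEG3", "GAD1", "GAD2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.055, Pu = 0.055}
correlation_block = 2
gradient_strength = 1.5

[[generator.populations]]
name = "SST/GRIK3"
marker_genes = ["SST", "GRIK3", "LHX6", "MEG3", "GAD1", "GAD2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.05, Pu = 0.05}
correlation_block = 3
gradient_strength = 1.5

[[generator.populations]]
name = "SST/NPY"
marker_genes = ["SST", "NPY", "LHX6", "MEG3", "GAD1", "GAD2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.055, Pu = 0.055}
correlation_block = 4
gradient_strength = 1.5

[[generator.populations]]
name = "SST/NPY/DACH1"
marker_genes = ["SST", "NPY", "DACH1", "LHX6", "MEG3", "GAD1", "GAD2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.055, Pu = 0.055}
correlation_block = 4
gradient_strength = 1.5

[[generator.populations]]
name = "PTHLH"
marker_genes = ["PTHLH", "OPN3", "LHX6", "MEG3", "GAD1", "GAD2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.105, Pu = 0.055}
correlation_block = 5
gradient_genes = ["GENE00101", "GENE00102", "GENE00103", "GENE00104", "GENE00105", "GENE00106", "GENE00107", "GENE00108", "GENE00109", "GENE00110", "GENE00111", "GENE00112", "GENE00113", "GENE00114", "GENE00115", "GENE00116", "GENE00117", "GENE00118", "GENE00119", "GENE00120", "GENE00121", "GENE00122", "GENE00123", "GENE00124", "GENE00125", "GENE00126", "GENE00127", "GENE00128", "GENE00129", "GENE00130", "GENE00131", "GENE00132", "GENE00133", "GENE00134", "GENE00135", "GENE00136", "GENE00137", "GENE00138", "GENE00139", "GENE00140"]
gradient_weights = [0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897]
gradient_strength = 1.5
planted_de = [["GENE00301", "CN", 1.04], ["GENE00302", "CN", 1.04], ["GENE00303", "CN", 1.04], ["GENE00304", "CN", 1.04], ["GENE00305", "CN", 1.04], ["GENE00306", "CN", 1.04], ["GENE00307", "CN", 1.04], ["GENE00308", "CN", 1.04], ["GENE00309", "CN", 1.04], ["GENE00310", "CN", 1.04], ["GENE00311", "CN", 1.04], ["GENE00312", "CN", 1.04], ["GENE00313", "Pu", 1.04], ["GENE00314", "Pu", 1.04], ["GENE00315", "Pu", 1.04], ["GENE00316", "Pu", 1.04], ["GENE00317", "Pu", 1.04], ["GENE00318", "Pu", 1.04], ["GENE00319", "Pu", 1.04], ["GENE00320", "Pu", 1.04], ["GENE00321", "Pu", 1.04], ["GENE00322", "Pu", 1.04], ["GENE00323", "Pu", 1.04], ["GENE00324", "Pu", 1.04]]

[[generator.populations]]
name = "PTHLH/MOXD1"
marker_genes = ["PTHLH", "OPN3", "MOXD1", "LHX6", "MEG3", "GAD1", "GAD2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.05, Pu = 0.05}
correlation_block = 5
gradient_strength = 1.5

[[generator.populations]]
name = "CHAT"
marker_genes = ["CHAT", "SLC5A7", "MEG3"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.05, Pu = 0.05}
correlation_block = 6
gradient_strength = 1.5

[[generator.populations]]
name = "TAC3"
marker_genes = ["TAC3", "PTPRK", "TMEM163", "GFRA2", "MEG3", "GAD1", "GAD2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.06, Pu = 0.06}
correlation_block = 7
gradient_genes = ["GENE00141", "GENE00142", "GENE00143", "GENE00144", "GENE00145", "GENE00146", "GENE00147", "GENE00148", "GENE00149", "GENE00150", "GENE00151", "GENE00152", "GENE00153", "GENE00154", "GENE00155", "GENE00156", "GENE00157", "GENE00158", "GENE00159", "GENE00160", "GENE00161", "GENE00162", "GENE00163", "GENE00164", "GENE00165", "GENE00166", "GENE00167", "GENE00168", "GENE00169", "GENE00170", "GENE00171", "GENE00172", "GENE00173", "GENE00174", "GENE00175", "GENE00176", "GENE00177", "GENE00178", "GENE00179", "GENE00180"]
gradient_weights = [0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897, 0.15811388300841897]
gradient_strength = 1.5

[[generator.populations]]
name = "TAC3/SEMA3A"
marker_genes = ["TAC3", "PTPRK", "SEMA3A", "MEG3", "GAD1", "GAD2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.05, Pu = 0.05}
correlation_block = 7
gradient_strength = 1.5

[[generator.populations]]
name = "astrocytes"
marker_genes = ["AQP4", "ADGRV1"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.05, Pu = 0.05}
correlation_block = 8
gradient_strength = 1.5

[[generator.populations]]
name = "microglia"
marker_genes = ["CSF1R", "FYB1"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.03, Pu = 0.03}
correlation_block = 9
gradient_strength = 1.5

[[generator.populations]]
name = "oligodendrocytes"
marker_genes = ["MBP", "MOG", "MAG", "MOBP", "OLIG1"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.05, Pu = 0.05}
correlation_block = 10
gradient_strength = 1.5

[[generator.populations]]
name = "OPC"
marker_genes = ["PTPRZ1", "PDGFRA", "VCAN", "OLIG1"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.02, Pu = 0.02}
correlation_block = 11
gradient_strength = 1.5

[[generator.populations]]
name = "vascular"
marker_genes = ["EBF1", "ABCB1", "ABCA9"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.02, Pu = 0.02}
correlation_block = 12
gradient_strength = 1.5

[[generator.populations]]
name = "MSN"
marker_genes = ["MEG3", "PPP1R1B", "DRD1", "DRD2", "MEIS2"]
marker_log_fold = 6.0
proportion_by_region = {CN = 0.05, Pu = 0.05}
correlation_block = 13
gradient_strength = 1.5

[qc]
min_umis = 500
min_genes = 1200
max_umis = 250000
max_genes = 15000
max_mito = 0.1
neuron_min_umis = 5000
neuron_min_genes = 3000
neuron_max_genes = 12000
doublet_vote_fraction = 0.1
n_doublet_runs = 15
poly_degree = 2
poly_outlier_delta = 2000.0
poly_outlier_log_scale = false
regional_min_expr = 0.0

[taxonomy]
target_sum = 10000.0
detect_n_hvg = 1500
detect_n_pcs = 30
detect_resolution = 0.2
subclass_n_hvg = 1500
subclass_n_pcs = 20
subclass_resolution = 1.0
knn = 15
positive_threshold = 0.25
negative_threshold = 0.1
label_margin = 0.05
merge_r_threshold = 0.49
merge_mode = "components"
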