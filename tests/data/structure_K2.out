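----------------------------------------------------
STRUCTURE by Pritchard, Stephens and Donnelly (2000)
     and Falush, Stephens and Pritchard (2003)
----------------------------------------------------

Run parameters:
   3 individuals
   3 loci
   2 populations assumed
   10000 Burn-in period
   20000 Reps

--------------------------------------------
Overall proportion of membership of the
sample in each of the 2 clusters

Inferred Clusters
  1      2
0.450  0.550

--------------------------------------------

Inferred ancestry of individuals:
        Label (%Miss)  :  Inferred clusters
  1        ind1    (0)   :  0.700 0.300
  2        ind2    (0)   :  0.200 0.800
  3        ind3    (0)   :  0.450 0.550


Estimated Allele Frequencies in each cluster
First column gives estimated ancestral frequencies


Locus 1 : snp1
2 alleles
0.0% missing data
   1   (0.550) 0.600 0.300
   2   (0.450) 0.400 0.700

Locus 2 : snp2
2 alleles
0.0% missing data
   1   (0.300) 0.250 0.350
   2   (0.700) 0.750 0.650

Locus 3 : msat1
3 alleles
0.0% missing data
   1   (0.200) 0.100 0.300
   2   (0.300) 0.400 0.200
   3   (0.500) 0.500 0.500

Values of parameters used in structure:
DATAFILE=project_data,	OUTFILE=results,	NUMINDS=3,	NUMLOCI=3,
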