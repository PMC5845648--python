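patient_id,group,biopsy_location,metric_name,value
Patient 1,Healthy,Right ventricle,cd90_total,1766
Patient 1,Healthy,Right ventricle,cd90_relative_number,6.964e-05
Patient 1,Healthy,Right ventricle,cd90_relative_area,0.00657148
Patient 1,Healthy,Right ventricle,cd117_relative_area,0.15489015
Patient 2,Healthy,Ventricle,cd90_total,986
Patient 2,Healthy,Ventricle,cd90_relative_number,0.00034775
Patient 2,Healthy,Ventricle,cd90_relative_area,0.02691154
Patient 2,Healthy,Ventricle,cd117_relative_area,0.00128155
Patient 3,Healthy,Ventricle,cd90_total,357
Patient 3,Healthy,Ventricle,cd90_relative_number,3.978e-05
Patient 3,Healthy,Ventricle,cd90_relative_area,0.00351804
Patient 3,Healthy,Ventricle,cd117_relative_area,0.02040115
Patient 4,Myocarditis,Septum,cd90_total,14493
Patient 4,Myocarditis,Septum,cd90_relative_number,0.00073061
Patient 4,Myocarditis,Septum,cd90_relative_area,0.08861789
Patient 4,Myocarditis,Septum,cd117_relative_area,0.28542232
Patient 5,Myocarditis,Septum,cd90_total,870
Patient 5,Myocarditis,Septum,cd90_relative_number,4.446e-05
Patient 5,Myocarditis,Septum,cd90_relative_area,0.00457649
Patient 5,Myocarditis,Septum,cd117_relative_area,0.60600118
Patient 6,Myocarditis,Septum,cd90_total,13860
Patient 6,Myocarditis,Septum,cd90_relative_number,0.00035446
Patient 6,Myocarditis,Septum,cd90_relative_area,0.04414038
Patient 6,Myocarditis,Septum,cd117_relative_area,0.64796254
Patient 7,ICM,Septum,cd90_total,3003
Patient 7,ICM,Septum,cd90_relative_number,9.935e-05
Patient 7,ICM,Septum,cd90_relative_area,0.00788957
Patient 7,ICM,Septum,cd117_relative_area,0.07027659
Patient 8,ICM,Left ventricle,cd90_total,7000
Patient 8,ICM,Left ventricle,cd90_relative_number,0.00021093
Patient 8,ICM,Left ventricle,cd90_relative_area,0.01858989
Patient 8,ICM,Left ventricle,cd117_relative_area,0.01535276
Patient 9,ICM,Left ventricle,cd90_total,1562
Patient 9,ICM,Left ventricle,cd90_relative_number,8.959e-05
Patient 9,ICM,Left ventricle,cd90_relative_area,0.00703351
Patient 9,ICM,Left ventricle,cd117_relative_area,0.41275665
Patient 10,ICM,Septum,cd90_total,3566
Patient 10,ICM,Septum,cd90_relative_number,0.00013633
Patient 10,ICM,Septum,cd90_relative_area,0.01256228
Patient 10,ICM,Septum,cd117_relative_area,0.40487681
Patient 11,ICM,Septum,cd90_total,1230
Patient 11,ICM,Septum,cd90_relative_number,6.138e-05
Patient 11,ICM,Septum,cd90_relative_area,0.00538673
Patient 11,ICM,Septum,cd117_relative_area,0.48448345
Patient 12,ICM,Septum,cd90_total,12254
Patient 12,ICM,Septum,cd90_relative_number,0.00055332
Patient 12,ICM,Septum,cd90_relative_area,0.04938569
Patient 12,ICM,Septum,cd117_relative_area,0.13488475
Patient 13,ICM,Left ventricle,cd90_total,1977
Patient 13,ICM,Left ventricle,cd90_relative_number,8.794e-05
Patient 13,ICM,Left ventricle,cd90_relative_area,0.00760771
Patient 13,ICM,Left ventricle,cd117_relative_area,0.48799854
Patient 14,ICM,Left ventricle,cd90_total,1190
Patient 14,ICM,Left ventricle,cd90_relative_number,0.0001929
Patient 14,ICM,Left ventricle,cd90_relative_area,0.01611067
Patient 14,ICM,Left ventricle,cd117_relative_area,0.57780017
Patient 15,ICM,Left ventricle,cd90_total,781
Patient 15,ICM,Left ventricle,cd90_relative_number,3.774e-05
Patient 15,ICM,Left ventricle,cd90_relative_area,0.00313921
Patient 15,ICM,Left ventricle,cd117_relative_area,0.41058415
Patient 16,ICM,Left ventricle,cd90_total,793
Patient 16,ICM,Left ventricle,cd90_relative_number,4.349e-05
Patient 16,ICM,Left ventricle,cd90_relative_area,0.00341586
Patient 16,ICM,Left ventricle,cd117_relative_area,0.32906417
Patient 17,DCM,Left ventricle,cd90_total,1634
Patient 17,DCM,Left ventricle,cd90_relative_number,5.087e-05
Patient 17,DCM,Left ventricle,cd90_relative_area,0.00423627
Patient 17,DCM,Left ventricle,cd117_relative_area,0.15127794
Patient 18,DCM,Septum,cd90_total,626
Patient 18,DCM,Septum,cd90_relative_number,4.535e-05
Patient 18,DCM,Septum,cd90_relative_area,0.00356114
Patient 18,DCM,Septum,cd117_relative_area,0.21075096
Patient 19,DCM,Septum,cd90_total,4203
Patient 19,DCM,Septum,cd90_relative_number,0.00022521
Patient 19,DCM,Septum,cd90_relative_area,0.01916202
Patient 19,DCM,Septum,cd117_relative_area,0.45260291
Patient 20,DCM,Left ventricle,cd90_total,1388
Patient 20,DCM,Left ventricle,cd90_relative_number,6.808e-05
Patient 20,DCM,Left ventricle,cd90_relative_area,0.00492588
Patient 20,DCM,Left ventricle,cd117_relative_area,0.3632407
Patient 21,DCM,Septum,cd90_total,96
Patient 21,DCM,Septum,cd90_relative_number,5.03e-06
Patient 21,DCM,Septum,cd90_relative_area,0.00120728
Patient 21,DCM,Septum,cd117_relative_area,0.36082968
Patient 22,DCM,Left ventricle,cd90_total,3251
Patient 22,DCM,Left ventricle,cd90_relative_number,8.052e-05
Patient 22,DCM,Left ventricle,cd90_relative_area,0.00644762
Patient 22,DCM,Left ventricle,cd117_relative_area,0.1610318
Patient 23,DCM,Septum,cd90_total,3808
Patient 23,DCM,Septum,cd90_relative_number,0.00011138
Patient 23,DCM,Septum,cd90_relative_area,0.00938711
Patient 23,DCM,Septum,cd117_relative_area,0.30622664
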